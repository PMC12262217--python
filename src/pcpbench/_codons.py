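"""Genetic-code lookup tables shared by the engines and the simulator.

Everything here is derived once, at import time, from biopython's standard
codon table. Codon outcomes are indexed 0..63 in lexicographic order over
the alphabet ``acgt``; amino acids are indexed 0..19 in alphabetical
one-letter order (``ACDEFGHIKLMNPQRSTVWY``).
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

BASES = "acgt"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}

CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

# (64, 3) base index of each codon position
CODON_BASE_IDX = np.array(
    [[BASE_INDEX[b] for b in codon] for codon in CODONS], dtype=np.intp
)

_fwd = {k.lower(): v for k, v in standard_dna_table.forward_table.items()}
STOP_CODONS = frozenset(c.lower() for c in standard_dna_table.stop_codons)

# amino-acid index per codon; -1 marks a stop codon
CODON_AA_IDX = np.array(
    [-1 if c in STOP_CODONS else AA_INDEX[_fwd[c]] for c in CODONS], dtype=np.intp
)
IS_STOP = CODON_AA_IDX < 0

# (64, 20) indicator: outcome codon c encodes amino acid a
CODON_AA_MATRIX = np.zeros((64, 20))
for _c in range(64):
    if not IS_STOP[_c]:
        CODON_AA_MATRIX[_c, CODON_AA_IDX[_c]] = 1.0

SENSE_CODON_INDICES = np.flatnonzero(~IS_STOP)


def codon_to_index(codon: str) -> int:
    """Index of a codon over {a,c,g,t}; raises KeyError for ambiguous codons."""
    return CODON_INDEX[codon.lower()]
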