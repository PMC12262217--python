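import itertools

import numpy as np
import pytest

from pcpbench.models import NTSiteRates

BASES = "acgt"


def make_random_rates(parent: str, rng: np.random.Generator) -> NTSiteRates:
    """Random per-site rates with Dirichlet conditional targets (wildtype 0)."""
    L = len(parent)
    lam = rng.uniform(0.1, 3.0, L)
    cp = np.zeros((L, 4))
    for i, b in enumerate(parent):
        targets = [j for j, x in enumerate(BASES) if x != b]
        cp[i, targets] = rng.dirichlet(np.ones(3))
    return NTSiteRates(lam=lam, cond_probs=cp)


def uniform_rates(parent: str, lam: float = 1.0) -> NTSiteRates:
    """Uniform rate lam with uniform conditional targets at every site."""
    L = len(parent)
    cp = np.zeros((L, 4))
    for i, b in enumerate(parent):
        if b not in BASES:  # ambiguous site: codon is skipped downstream
            cp[i] = 0.25
            continue
        targets = [j for j, x in enumerate(BASES) if x != b]
        cp[i, targets] = 1.0 / 3.0
    return NTSiteRates(lam=np.full(L, lam), cond_probs=cp)


def brute_force_codon_aa(parent_codon: str, P: np.ndarray, stay: np.ndarray) -> dict:
    """Independent oracle: enumerate all 64 codon outcomes, drop stops,
    renormalize, and aggregate amino-acid mass by biopython translation."""
    from Bio.Seq import Seq

    probs = {}
    for out in itertools.product(BASES, repeat=3):
        codon = "".join(out)
        p = 1.0
        for j, b in enumerate(out):
            p *= stay[j] if b == parent_codon[j] else P[j, BASES.index(b)]
        if str(Seq(codon).translate()) == "*":
            continue
        probs[codon] = p
    z = sum(probs.values())
    aa_mass: dict[str, float] = {}
    for codon, p in probs.items():
        aa = str(Seq(codon).translate())
        aa_mass[aa] = aa_mass.get(aa, 0.0) + p / z
    return aa_mass


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
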