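"""Reading, validating, filtering, and annotating parent-child pairs (PCPs).

A PCP is one branch of a reconstructed B-cell lineage: an aligned parent and
child nucleotide sequence of equal length (a multiple of 3), plus metadata
and an optional per-codon-site IMGT position map used for regional analysis.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._codons import STOP_CODONS, _fwd

__all__ = [
    "PCP",
    "RegionScheme",
    "FilterReport",
    "PCPRecordError",
    "MalformedRecordsError",
    "read_pcps",
    "write_pcps",
    "translate",
    "filter_pcps",
    "window_mutation_filter",
    "annotate_regions",
]

_NT_ALPHABET = set("acgtn")


class PCPRecordError(ValueError):
    """A single malformed PCP record; carries the source line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class MalformedRecordsError(ValueError):
    """Raised after reading when one or more records were malformed."""

    def __init__(self, errors: list[PCPRecordError]):
        self.errors = errors
        lines = "; ".join(str(e) for e in errors)
        super().__init__(f"{len(errors)} malformed PCP record(s): {lines}")


@dataclass(frozen=True)
class PCP:
    """One parent-child pair of aligned BCR nucleotide sequences.

    ``position_map``, when present, gives one IMGT position label (a string,
    to allow insertion codes such as ``"111.1"``) per codon site.
    """

    pcp_id: str
    family_id: str
    parent_nt: str
    child_nt: str
    position_map: tuple[str, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "parent_nt", self.parent_nt.lower())
        object.__setattr__(self, "child_nt", self.child_nt.lower())
        if len(self.parent_nt) != len(self.child_nt):
            raise PCPRecordError(
                f"pcp {self.pcp_id!r}: parent length {len(self.parent_nt)} != "
                f"child length {len(self.child_nt)}"
            )
        if len(self.parent_nt) % 3 != 0:
            raise PCPRecordError(
                f"pcp {self.pcp_id!r}: length {len(self.parent_nt)} is not a multiple of 3"
            )
        for name, seq in (("parent", self.parent_nt), ("child", self.child_nt)):
            bad = set(seq) - _NT_ALPHABET
            if bad:
                raise PCPRecordError(
                    f"pcp {self.pcp_id!r}: {name} has characters outside acgtn: {sorted(bad)}"
                )
        if self.position_map is not None:
            pm = tuple(str(p) for p in self.position_map)
            if len(pm) != self.n_codons:
                raise PCPRecordError(
                    f"pcp {self.pcp_id!r}: position map has {len(pm)} entries "
                    f"for {self.n_codons} codon sites"
                )
            object.__setattr__(self, "position_map", pm)

    @property
    def n_codons(self) -> int:
        return len(self.parent_nt) // 3

    @property
    def parent_aa(self) -> str:
        return translate(self.parent_nt)

    @property
    def child_aa(self) -> str:
        return translate(self.child_nt)

    def nt_mutation_count(self) -> int:
        """Mismatching nucleotide sites, ignoring sites with an ``n``."""
        return sum(
            1
            for p, c in zip(self.parent_nt, self.child_nt)
            if p != c and p != "n" and c != "n"
        )

    def aa_substitutions(self) -> list[tuple[int, str, str]]:
        """(codon site, parent aa, child aa) at unambiguous differing sites."""
        out = []
        for r, (p, c) in enumerate(zip(self.parent_aa, self.child_aa)):
            if p != c and p not in "X*" and c not in "X*":
                out.append((r, p, c))
        return out

    def codon_site_mask(self) -> list[bool]:
        """True for codon sites free of ``n`` in both parent and child."""
        mask = []
        for r in range(self.n_codons):
            s = slice(3 * r, 3 * r + 3)
            mask.append("n" not in self.parent_nt[s] and "n" not in self.child_nt[s])
        return mask

    def effective_position_map(self) -> tuple[str, ...]:
        """The position map, defaulting to the identity map (site i -> "i+1")."""
        if self.position_map is not None:
            return self.position_map
        return tuple(str(i + 1) for i in range(self.n_codons))


def translate(nt: str) -> str:
    """Translate a nucleotide string with the standard genetic code.

    Codons containing ``n`` (or otherwise ambiguous) yield ``X``; stop codons
    yield ``*``. The length must be a multiple of 3.
    """
    nt = nt.lower()
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(_fwd.get(codon, "X"))
    return "".join(out)


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = ("pcp_id", "family_id", "parent_nt", "child_nt")


def read_pcps(path: str | Path, format: str = "tsv") -> list[PCP]:
    """Read PCPs from a TSV file or the interleaved FASTA-pairs dialect.

    TSV columns: ``pcp_id``, ``family_id``, ``parent_nt``, ``child_nt`` and an
    optional ``position_map`` (comma-separated IMGT labels). FASTA-pairs holds
    interleaved ``>id|parent`` / ``>id|child`` records.

    Raises :class:`MalformedRecordsError` listing every bad row (with line
    numbers) if any record fails validation; a missing column is fatal
    immediately.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "fasta-pairs":
        return _read_fasta_pairs(path)
    raise ValueError(f"unknown PCP format {format!r}")


def _read_tsv(path: Path) -> list[PCP]:
    pcps: list[PCP] = []
    errors: list[PCPRecordError] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = set(_TSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
        has_map = "position_map" in reader.fieldnames
        for lineno, row in enumerate(reader, start=2):
            try:
                pm = None
                if has_map and row.get("position_map"):
                    pm = tuple(row["position_map"].split(","))
                pcps.append(
                    PCP(
                        pcp_id=row["pcp_id"],
                        family_id=row["family_id"],
                        parent_nt=row["parent_nt"],
                        child_nt=row["child_nt"],
                        position_map=pm,
                    )
                )
            except PCPRecordError as err:
                errors.append(PCPRecordError(str(err), line=lineno))
    if errors:
        raise MalformedRecordsError(errors)
    return pcps


def _read_fasta_pairs(path: Path) -> list[PCP]:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise ValueError(f"{path}: odd number of FASTA records in pairs file")
    pcps: list[PCP] = []
    errors: list[PCPRecordError] = []
    for i in range(0, len(records), 2):
        par, chi = records[i], records[i + 1]
        pid, prole = par.id.rsplit("|", 1)
        cid, crole = chi.id.rsplit("|", 1)
        if pid != cid or prole != "parent" or crole != "child":
            raise ValueError(
                f"{path}: records {par.id!r}/{chi.id!r} are not a parent/child pair"
            )
        try:
            pcps.append(
                PCP(pcp_id=pid, family_id=pid, parent_nt=str(par.seq), child_nt=str(chi.seq))
            )
        except PCPRecordError as err:
            errors.append(PCPRecordError(str(err), line=2 * i + 1))
    if errors:
        raise MalformedRecordsError(errors)
    return pcps


def write_pcps(pcps: Iterable[PCP], path: str | Path) -> None:
    """Write PCPs as canonical TSV (round-trips with :func:`read_pcps`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS + ("position_map",))
        for p in pcps:
            pm = ",".join(p.position_map) if p.position_map is not None else ""
            writer.writerow([p.pcp_id, p.family_id, p.parent_nt, p.child_nt, pm])


# ---------------------------------------------------------------------------
# Filtering

@dataclass
class FilterReport:
    """Tally of PCPs dropped per filtering rule."""

    n_input: int = 0
    dropped: dict[str, int] = field(
        default_factory=lambda: {
            "stop_codon": 0,
            "high_substitution_frequency": 0,
            "no_aa_substitution": 0,
        }
    )

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.dropped.values())

    def to_json(self) -> str:
        return json.dumps(
            {"n_input": self.n_input, "dropped": self.dropped, "n_retained": self.n_retained},
            indent=2,
        )


def filter_pcps(
    pcps: Sequence[PCP], max_sub_frequency: float = 0.30
) -> tuple[list[PCP], FilterReport]:
    """Apply the standard PCP quality filters, in order.

    Drops (1) PCPs whose parent or child translation contains a stop codon,
    (2) PCPs whose nucleotide substitution frequency (mutated sites / length)
    exceeds ``max_sub_frequency`` — highly diverged branches are suspect —
    and (3) PCPs with no amino-acid substitution at all.
    """
    report = FilterReport(n_input=len(pcps))
    kept: list[PCP] = []
    for p in pcps:
        if "*" in p.parent_aa or "*" in p.child_aa:
            report.dropped["stop_codon"] += 1
            continue
        if p.nt_mutation_count() / len(p.parent_nt) > max_sub_frequency:
            report.dropped["high_substitution_frequency"] += 1
            continue
        if not p.aa_substitutions():
            report.dropped["no_aa_substitution"] += 1
            continue
        kept.append(p)
    return kept, report


def window_mutation_filter(
    parent: str, reference: str, window: int = 20, max_mut: int = 10
) -> bool:
    """True (keep) iff no window of ``window`` consecutive sites has more than
    ``max_mut`` mismatches against the reference.

    Intended as an optional pre-filter against an inferred naive sequence to
    remove sequences whose dense local mutation clusters suggest sequencing
    or inference artifacts.
    """
    parent, reference = parent.lower(), reference.lower()
    if len(parent) != len(reference):
        raise ValueError("parent and reference lengths differ")
    mism = [1 if a != b else 0 for a, b in zip(parent, reference)]
    w = min(window, len(mism))
    if w == 0:
        return True
    total = sum(mism[:w])
    if total > max_mut:
        return False
    for i in range(w, len(mism)):
        total += mism[i] - mism[i - w]
        if total > max_mut:
            return False
    return True


# ---------------------------------------------------------------------------
# Region annotation

#: IMGT unique-numbering boundaries of the framework (FWR) and
#: complementarity-determining (CDR) regions of an antibody variable domain.
IMGT_REGIONS: dict[str, tuple[int, int]] = {
    "FWR1": (1, 26),
    "CDR1": (27, 38),
    "FWR2": (39, 55),
    "CDR2": (56, 65),
    "FWR3": (66, 104),
    "CDR3": (105, 117),
    "FWR4": (118, 128),
}

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class RegionScheme:
    """Inclusive IMGT position ranges per region; defaults to the standard
    IMGT variable-domain definitions."""

    region_bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(IMGT_REGIONS)
    )

    def __post_init__(self):
        ranges = sorted(self.region_bounds.values())
        for (lo1, hi1), (lo2, _) in zip(ranges, ranges[1:]):
            if lo1 > hi1 or hi1 >= lo2:
                raise ValueError("region ranges must be ordered and disjoint")

    def region_of(self, imgt_label: str) -> str:
        """Region name for an IMGT position label, or ``"unassigned"`` for
        insertion codes and positions outside every range."""
        try:
            pos = int(imgt_label)
        except ValueError:
            return UNASSIGNED
        for name, (lo, hi) in self.region_bounds.items():
            if lo <= pos <= hi:
                return name
        return UNASSIGNED


def annotate_regions(pcp: PCP, scheme: RegionScheme | None = None) -> list[str]:
    """Region label per codon site using the PCP's position map (identity map
    if absent, which suits synthetic data)."""
    scheme = scheme or RegionScheme()
    return [scheme.region_of(lbl) for lbl in pcp.effective_position_map()]
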