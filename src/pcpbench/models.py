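"""Model contracts for the three evaluation frameworks.

Three kinds of model feed the evaluation engines:

* **NT mutation models** produce, for each nucleotide site of a parent
  sequence, a neutral rate ``lambda_i`` and a conditional mutation
  probability vector over target bases (zero at the wildtype base) —
  k-mer context tables and per-site rate tables are both supported;
* **selection models** produce, per codon site and candidate amino acid,
  a preference ratio ``R`` of child over parent (BLOSUM62 log-odds or
  deep-mutational-scan binding measurements);
* **AA sequence models** produce per-site logits over the 20 amino acids
  (the contract masked-language-model adapters fulfil; logits are consumed
  from precomputed tables so no model weights are required).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.special import softmax

from ._codons import AA_INDEX, AA_LETTERS, BASE_INDEX, BASES

__all__ = [
    "NTSiteRates",
    "KmerModelTable",
    "PerSiteRateModel",
    "DMSMeasurements",
    "AASiteLogits",
    "kmer_rates",
    "per_site_rates",
    "blosum62_matrix",
    "blosum_ratios",
    "dms_ratios",
    "logits_to_probabilities",
    "read_kmer_model",
    "write_kmer_model",
    "read_per_site_model",
    "read_dms",
    "read_logits",
    "write_logits",
]


@dataclass(frozen=True)
class NTSiteRates:
    """Per-nucleotide-site neutral rates and conditional mutation targets.

    ``lam[i]`` is the rate of the exponential waiting time until mutation at
    site i; ``cond_probs[i]`` is the distribution over the target base given
    that a mutation occurred (so the wildtype entry is zero).
    """

    lam: np.ndarray            # (L,) nonnegative
    cond_probs: np.ndarray     # (L, 4) rows sum to 1

    def __post_init__(self):
        lam = np.asarray(self.lam, dtype=float)
        cp = np.asarray(self.cond_probs, dtype=float)
        if lam.ndim != 1 or cp.shape != (lam.size, 4):
            raise ValueError("lam must be (L,) and cond_probs (L, 4)")
        if np.any(lam < 0):
            raise ValueError("rates must be nonnegative")
        if np.any(cp < 0) or not np.allclose(cp.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("conditional probability rows must be nonnegative and sum to 1")
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "cond_probs", cp)

    def __len__(self) -> int:
        return self.lam.size


def _zero_wildtype(profile: np.ndarray, base_idx: int) -> np.ndarray:
    """Zero the wildtype entry of a 4-vector and renormalize."""
    out = profile.copy()
    out[base_idx] = 0.0
    s = out.sum()
    if s <= 0:
        # degenerate profile: fall back to uniform over the three targets
        out[:] = 1.0
        out[base_idx] = 0.0
        s = 3.0
    return out / s


@dataclass
class KmerModelTable:
    """k-mer context model: the mutability of a site is read from the k-mer
    centered on it (the classic 5-mer SHM-model form).

    Contexts that run past a sequence end are padded with ``n`` and resolved
    through the ``default_rate`` / ``default_profile`` entry.
    """

    k: int
    rate: Mapping[str, float]
    cond_probs: Mapping[str, np.ndarray]
    default_rate: float | None = None
    default_profile: np.ndarray | None = None
    name: str = "kmer"

    def __post_init__(self):
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError(f"k must be odd and positive, got {self.k}")
        for kmer, row in self.cond_probs.items():
            row = np.asarray(row, dtype=float)
            center = kmer[self.k // 2]
            if row[BASE_INDEX[center]] != 0:
                raise ValueError(f"k-mer {kmer!r}: wildtype conditional probability must be 0")
            if not np.isclose(row.sum(), 1.0, atol=1e-8):
                raise ValueError(f"k-mer {kmer!r}: conditional probabilities must sum to 1")


def kmer_rates(model: KmerModelTable, parent_nt: str) -> NTSiteRates:
    """Evaluate a k-mer model on a parent sequence.

    Site ``i`` gets the table entry for the k-mer centered at ``i``; contexts
    containing ``n`` (padding or ambiguity) use the model's default entry
    with the wildtype base zeroed out.
    """
    parent_nt = parent_nt.lower()
    h = model.k // 2
    padded = "n" * h + parent_nt + "n" * h
    L = len(parent_nt)
    lam = np.empty(L)
    cp = np.empty((L, 4))
    for i in range(L):
        kmer = padded[i : i + model.k]
        base = parent_nt[i]
        if kmer in model.rate:
            lam[i] = model.rate[kmer]
            cp[i] = model.cond_probs[kmer]
        else:
            if model.default_rate is None or model.default_profile is None:
                raise KeyError(
                    f"k-mer {kmer!r} (site {i}) absent from model {model.name!r} "
                    "and no default entry supplied"
                )
            lam[i] = model.default_rate
            if base in BASE_INDEX:
                cp[i] = _zero_wildtype(np.asarray(model.default_profile, float), BASE_INDEX[base])
            else:
                # base is n: the codon will be skipped downstream anyway
                cp[i] = np.full(4, 0.25)
    return NTSiteRates(lam=lam, cond_probs=cp)


@dataclass
class PerSiteRateModel:
    """Per-site mutation probabilities for one fixed reference (naive)
    sequence, softmax-normalized so the rates over all sites sum to 1.

    This is the form of passenger-derived SHM models fit to a single known
    naive sequence: rates are indexed by naive-sequence coordinate and do
    not depend on the current parent's bases.
    """

    rates: np.ndarray          # (L,) sums to 1
    cond_probs: np.ndarray     # (L, 4)
    name: str = "per-site"

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.cond_probs = np.asarray(self.cond_probs, dtype=float)
        if not np.isclose(self.rates.sum(), 1.0, atol=1e-6):
            raise ValueError("per-site rates must sum to 1 (softmax parametrization)")
        if self.cond_probs.shape != (self.rates.size, 4):
            raise ValueError("cond_probs must be (L, 4)")


def per_site_rates(model: PerSiteRateModel, parent_nt: str) -> NTSiteRates:
    """Rates for a parent under the naive-context assumption: taken verbatim
    from the table regardless of the parent's current bases."""
    if len(parent_nt) != model.rates.size:
        raise ValueError(
            f"parent length {len(parent_nt)} != model reference length {model.rates.size}"
        )
    return NTSiteRates(lam=model.rates.copy(), cond_probs=model.cond_probs.copy())


# ---------------------------------------------------------------------------
# Selection models: per-site x amino-acid preference ratios R

def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 log-odds entries as a (20, 20) array in alphabetical
    one-letter amino-acid order."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20))
    for i, a in enumerate(AA_LETTERS):
        for j, b in enumerate(AA_LETTERS):
            out[i, j] = m[a, b]
    return out


def blosum_ratios(M: np.ndarray, parent_aa: str) -> np.ndarray:
    """Preference ratios from a half-bit log-odds matrix: R = 2^(M[X',X]/2)
    for candidate X' against parent X, with R = 1 at the wildtype.

    Returns an (n_sites, 20) array.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (20, 20):
        raise ValueError("substitution matrix must be 20x20")
    try:
        parent_idx = np.array([AA_INDEX[a] for a in parent_aa])
    except KeyError as err:
        raise ValueError(f"nonstandard amino acid {err.args[0]!r} in parent") from None
    R = 2.0 ** (M[:, parent_idx].T / 2.0)
    R[np.arange(len(parent_aa)), parent_idx] = 1.0
    return R


@dataclass
class DMSMeasurements:
    """Deep-mutational-scan binding strengths, -log10(KD), for every single
    amino-acid mutant relative to a fixed naive sequence.

    ``binding[r, a]`` is the measurement for amino acid ``a`` at codon site
    ``r``; NaN marks a missing measurement.
    """

    binding: np.ndarray        # (n_sites, 20), -log10 KD
    name: str = "dms"

    def __post_init__(self):
        self.binding = np.asarray(self.binding, dtype=float)
        if self.binding.ndim != 2 or self.binding.shape[1] != 20:
            raise ValueError("binding must be (n_sites, 20)")


def dms_ratios(dms: DMSMeasurements, parent_aa: str, missing_ratio: float = 1.0) -> np.ndarray:
    """Dissociation-constant ratios R = KD(parent)/KD(child) from binding
    strengths b = -log10 KD: R = 10^(b_child - b_parent).

    Missing entries (NaN, including a missing wildtype) fall back to
    ``missing_ratio`` with a warning.
    """
    if len(parent_aa) > dms.binding.shape[0]:
        raise ValueError(
            f"parent has {len(parent_aa)} sites but DMS covers {dms.binding.shape[0]}"
        )
    parent_idx = np.array([AA_INDEX[a] for a in parent_aa])
    rows = np.arange(len(parent_aa))
    b = dms.binding[: len(parent_aa)]
    b_parent = b[rows, parent_idx]
    with np.errstate(invalid="ignore"):
        R = 10.0 ** (b - b_parent[:, None])
    missing = ~np.isfinite(R)
    if missing.any():
        warnings.warn(
            f"{missing.sum()} missing DMS entries replaced with R={missing_ratio}",
            stacklevel=2,
        )
        R = np.where(missing, missing_ratio, R)
    R[rows, parent_idx] = 1.0
    return R


# ---------------------------------------------------------------------------
# AA sequence models

@dataclass
class AASiteLogits:
    """Per-site logits over the 20 standard amino acids for one parent
    protein, as produced by a masked language model.

    ``strategy`` records how the logits were generated — ``masked-marginals``
    (one forward pass per masked site; parent-independent at the site) or
    ``wt-marginals`` (single unmasked pass) — and is metadata only: both are
    treated identically downstream.
    """

    logits: np.ndarray         # (n_sites, 20)
    strategy: str = "masked-marginals"

    def __post_init__(self):
        self.logits = np.asarray(self.logits, dtype=float)
        if self.logits.ndim != 2 or self.logits.shape[1] != 20:
            raise ValueError("logits must be (n_sites, 20)")
        if not np.all(np.isfinite(self.logits)):
            raise ValueError("logits must be finite")
        if self.strategy not in ("masked-marginals", "wt-marginals"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def logits_to_probabilities(logits: AASiteLogits) -> np.ndarray:
    """Softmax per site over the 20 standard amino acids; rows sum to 1."""
    return softmax(logits.logits, axis=1)


# ---------------------------------------------------------------------------
# Table I/O (all plain TSV)

_PROFILE_COLS = ["p_a", "p_c", "p_g", "p_t"]


def read_kmer_model(path: str | Path, name: str | None = None) -> KmerModelTable:
    """Read a k-mer model table: TSV with columns kmer, rate, p_a, p_c, p_g,
    p_t. A row with kmer ``default`` supplies the fallback for n-containing
    contexts."""
    df = pd.read_csv(path, sep="\t", dtype={"kmer": str})
    rate: dict[str, float] = {}
    cond: dict[str, np.ndarray] = {}
    default_rate = None
    default_profile = None
    k = None
    for _, row in df.iterrows():
        kmer = row["kmer"].lower()
        profile = row[_PROFILE_COLS].to_numpy(dtype=float)
        if kmer == "default":
            default_rate = float(row["rate"])
            default_profile = profile
            continue
        if k is None:
            k = len(kmer)
        elif len(kmer) != k:
            raise ValueError(f"{path}: inconsistent k-mer width at {kmer!r}")
        rate[kmer] = float(row["rate"])
        cond[kmer] = profile
    if k is None:
        raise ValueError(f"{path}: no k-mer rows")
    return KmerModelTable(
        k=k,
        rate=rate,
        cond_probs=cond,
        default_rate=default_rate,
        default_profile=default_profile,
        name=name or Path(path).stem,
    )


def write_kmer_model(model: KmerModelTable, path: str | Path) -> None:
    rows = []
    for kmer in sorted(model.rate):
        rows.append([kmer, model.rate[kmer], *np.asarray(model.cond_probs[kmer], float)])
    if model.default_rate is not None:
        rows.append(["default", model.default_rate, *np.asarray(model.default_profile, float)])
    pd.DataFrame(rows, columns=["kmer", "rate", *_PROFILE_COLS]).to_csv(
        path, sep="\t", index=False
    )


def read_per_site_model(path: str | Path, name: str | None = None) -> PerSiteRateModel:
    """Read a per-site rate table: TSV with columns site (0-based), rate,
    p_a, p_c, p_g, p_t."""
    df = pd.read_csv(path, sep="\t").sort_values("site")
    if not np.array_equal(df["site"].to_numpy(), np.arange(len(df))):
        raise ValueError(f"{path}: sites must be contiguous from 0")
    return PerSiteRateModel(
        rates=df["rate"].to_numpy(dtype=float),
        cond_probs=df[_PROFILE_COLS].to_numpy(dtype=float),
        name=name or Path(path).stem,
    )


def read_dms(path: str | Path, name: str | None = None) -> DMSMeasurements:
    """Read DMS binding measurements: TSV with columns site (0-based), aa,
    neg_log10_kd."""
    df = pd.read_csv(path, sep="\t")
    n_sites = int(df["site"].max()) + 1
    binding = np.full((n_sites, 20), np.nan)
    for _, row in df.iterrows():
        binding[int(row["site"]), AA_INDEX[row["aa"]]] = float(row["neg_log10_kd"])
    return DMSMeasurements(binding=binding, name=name or Path(path).stem)


def read_logits(path: str | Path) -> dict[str, AASiteLogits]:
    """Read per-PCP logit tables: a ``# strategy: ...`` header line followed
    by TSV columns pcp_id, site, and the 20 amino-acid letters."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    strategy = "masked-marginals"
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "strategy:" in first:
            strategy = first.split("strategy:", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    out: dict[str, AASiteLogits] = {}
    aa_cols = list(AA_LETTERS)
    for pcp_id, grp in df.groupby("pcp_id", sort=False):
        grp = grp.sort_values("site")
        out[str(pcp_id)] = AASiteLogits(
            logits=grp[aa_cols].to_numpy(dtype=float), strategy=strategy
        )
    return out


def write_logits(tables: Mapping[str, AASiteLogits], path: str | Path) -> None:
    strategies = {t.strategy for t in tables.values()}
    if len(strategies) > 1:
        raise ValueError("all logit tables in one file must share a strategy")
    strategy = strategies.pop() if strategies else "masked-marginals"
    with open(path, "w") as fh:
        fh.write(f"# strategy: {strategy}\n")
        fh.write("pcp_id\tsite\t" + "\t".join(AA_LETTERS) + "\n")
        for pcp_id, table in tables.items():
            for site, row in enumerate(table.logits):
                vals = "\t".join(repr(float(v)) for v in row)
                fh.write(f"{pcp_id}\t{site}\t{vals}\n")
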