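"""Synthetic PCP datasets with known ground truth.

Children are sampled per codon from the exact codon-outcome distribution the
engines use for likelihood evaluation (single-hit exponential-waiting-time
mutation, optional selection factors, stop outcomes excluded). Simulation and
evaluation therefore share one code path, which makes parameter-recovery and
calibration tests sharp: the generating model is, by construction, the model
under which the data were produced.

Ground truth (true tau, per-site SSPs under the generating model, mutated
site lists, and resample counts) is emitted alongside the sequences so tests
can condition correctly on the ascertainment introduced by requiring at
least one amino-acid substitution per PCP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._codons import CODONS, SENSE_CODON_INDICES
from .engines import (
    SelectionProfile,
    codon_outcome_probs,
    codon_aa_distribution,
    apply_selection,
)
from .metrics import site_substitution_probability
from .models import KmerModelTable, NTSiteRates, kmer_rates
from .pcp_io import PCP, write_pcps

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "random_parent",
    "random_kmer_model",
    "permute_kmer_model",
    "simulate_child",
    "generate_dataset",
    "generate_pcps",
]

#: Retry cap when a configuration requires >= 1 amino-acid substitution.
MAX_RESAMPLES = 1000


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a realistic antibody-lineage branch set: heavy-chain
    variable regions are ~100 codons (length 300 nt) and branch lengths of
    real parent-child pairs put a handful of nucleotide mutations on most
    branches, so tau is drawn log-uniformly over [0.01, 0.3] with unit-scale
    context rates.
    """

    n_pcps: int = 500
    length: int = 300
    tau_range: tuple[float, float] = (0.01, 0.3)
    fixed_tau: float | None = None
    seed: int = 0
    kmer_k: int = 3
    require_aa_substitution: bool = True

    def __post_init__(self):
        if self.length % 3 != 0:
            raise ValueError(f"length {self.length} is not a multiple of 3")
        if self.n_pcps < 1:
            raise ValueError("n_pcps must be >= 1")


@dataclass
class TruthRecord:
    """Per-PCP ground truth for a generated dataset."""

    tau: dict[str, float] = field(default_factory=dict)
    ssp: dict[str, list[float]] = field(default_factory=dict)
    mutated_sites: dict[str, list[int]] = field(default_factory=dict)
    n_resamples: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "tau": self.tau,
                "ssp": self.ssp,
                "mutated_sites": self.mutated_sites,
                "n_resamples": self.n_resamples,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            tau=d["tau"],
            ssp=d["ssp"],
            mutated_sites=d["mutated_sites"],
            n_resamples=d["n_resamples"],
        )


def random_parent(length: int, rng: np.random.Generator) -> str:
    """Uniform sense-codon nucleotide sequence (stop codons rejected)."""
    if length % 3 != 0:
        raise ValueError(f"length {length} is not a multiple of 3")
    idx = rng.choice(SENSE_CODON_INDICES, size=length // 3)
    return "".join(CODONS[i] for i in idx)


def random_kmer_model(
    k: int = 3, seed: int = 0, rate_sigma: float = 0.5, name: str = "synthetic-kmer"
) -> KmerModelTable:
    """A synthetic k-mer SHM-like context model.

    Rates are log-normal(0, ``rate_sigma``) around 1 — unit scale so tau is
    interpretable as expected mutations per site — and conditional target
    probabilities are Dirichlet(1) over the three non-wildtype bases, mimicking
    the heavy-tailed hot/cold-spot structure of real mutability tables.
    """
    rng = np.random.default_rng(seed)
    h = k // 2
    bases = "acgt"
    kmers = []

    def build(prefix):
        if len(prefix) == k:
            kmers.append(prefix)
            return
        for b in bases:
            build(prefix + b)

    build("")
    rate = {}
    cond = {}
    for kmer in kmers:
        rate[kmer] = float(rng.lognormal(mean=0.0, sigma=rate_sigma))
        profile = np.zeros(4)
        targets = [i for i, b in enumerate(bases) if b != kmer[h]]
        profile[targets] = rng.dirichlet(np.ones(3))
        cond[kmer] = profile
    return KmerModelTable(
        k=k,
        rate=rate,
        cond_probs=cond,
        default_rate=1.0,
        default_profile=np.full(4, 0.25),
        name=name,
    )


def permute_kmer_model(
    model: KmerModelTable, seed: int = 0, name: str | None = None
) -> KmerModelTable:
    """A mismatched null model: the k-mer -> rate assignment is permuted
    (conditional profiles follow their k-mer's central base constraint but are
    permuted among k-mers sharing that base)."""
    rng = np.random.default_rng(seed)
    h = model.k // 2
    kmers = sorted(model.rate)
    perm_rates = rng.permutation([model.rate[m] for m in kmers])
    rate = {m: float(r) for m, r in zip(kmers, perm_rates)}
    cond = {}
    by_center: dict[str, list[str]] = {}
    for m in kmers:
        by_center.setdefault(m[h], []).append(m)
    for center, group in by_center.items():
        shuffled = list(group)
        rng.shuffle(shuffled)
        for src, dst in zip(group, shuffled):
            cond[dst] = model.cond_probs[src]
    return KmerModelTable(
        k=model.k,
        rate=rate,
        cond_probs=cond,
        default_rate=model.default_rate,
        default_profile=model.default_profile,
        name=name or f"{model.name}-permuted",
    )


def simulate_child(
    parent: str,
    rates: NTSiteRates,
    tau: float,
    selection: SelectionProfile | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Sample a child sequence: per codon site, one draw from the 61-sense
    outcome distribution produced by the evaluation engine."""
    rng = rng or np.random.default_rng()
    factors = selection.factors if selection is not None else None
    probs64, codon_idx = codon_outcome_probs(rates, parent, tau, factors=factors)
    out = []
    for r in range(codon_idx.size):
        if codon_idx[r] < 0:
            out.append(parent[3 * r : 3 * r + 3])
            continue
        c = rng.choice(64, p=probs64[r])
        out.append(CODONS[c])
    return "".join(out)


def _pcp_rng(master_seed: int, index: int) -> np.random.Generator:
    # counter-based stream per PCP: changing n_pcps never reshuffles earlier PCPs
    return np.random.default_rng([master_seed, index])


def generate_pcps(
    config: SimulationConfig,
    model: KmerModelTable | None = None,
    selection: SelectionProfile | None = None,
) -> tuple[list[PCP], TruthRecord, KmerModelTable]:
    """Generate PCPs in memory under a k-mer generating model.

    If ``model`` is None a synthetic context model is drawn deterministically
    from the config seed. When ``require_aa_substitution`` is set, children
    are resampled (fresh tau each attempt) until the pair carries at least
    one amino-acid substitution; the truth record keeps the resample count
    per PCP so calibration tests can account for the ascertainment.
    """
    model = model or random_kmer_model(k=config.kmer_k, seed=config.seed)
    truth = TruthRecord()
    pcps: list[PCP] = []
    lo, hi = config.tau_range
    for i in range(config.n_pcps):
        rng = _pcp_rng(config.seed, i)
        parent = random_parent(config.length, rng)
        rates = kmer_rates(model, parent)
        attempts = 0
        while True:
            if config.fixed_tau is not None:
                tau = config.fixed_tau
            else:
                tau = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            child = simulate_child(parent, rates, tau, selection=selection, rng=rng)
            pcp = PCP(pcp_id=f"pcp{i}", family_id=f"fam{i}", parent_nt=parent, child_nt=child)
            if not config.require_aa_substitution or pcp.aa_substitutions():
                break
            attempts += 1
            if attempts >= MAX_RESAMPLES:
                raise RuntimeError(
                    f"pcp{i}: no amino-acid substitution after {MAX_RESAMPLES} resamples; "
                    "tau range is too small for the configured length"
                )
        if selection is None:
            dist = codon_aa_distribution(rates, parent, tau)
        else:
            dist = apply_selection(rates, parent, selection, tau)
        ssp = site_substitution_probability(dist)
        truth.tau[pcp.pcp_id] = tau
        truth.ssp[pcp.pcp_id] = [float(v) for v in ssp]
        truth.mutated_sites[pcp.pcp_id] = [r for r, _, _ in pcp.aa_substitutions()]
        truth.n_resamples[pcp.pcp_id] = attempts
        pcps.append(pcp)
    return pcps, truth, model


def generate_dataset(
    config: SimulationConfig,
    out_dir: str | Path,
    model: KmerModelTable | None = None,
    selection: SelectionProfile | None = None,
) -> tuple[Path, Path]:
    """Generate a dataset and write ``pcps.tsv`` plus ``truth.json``.

    Returns the two paths. Runs are byte-identical for a fixed config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pcps, truth, _ = generate_pcps(config, model=model, selection=selection)
    pcp_path = out_dir / "pcps.tsv"
    truth_path = out_dir / "truth.json"
    write_pcps(pcps, pcp_path)
    truth_path.write_text(truth.to_json())
    return pcp_path, truth_path
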