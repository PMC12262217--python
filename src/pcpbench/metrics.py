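"""Performance metrics for substitution predictions.

Two prediction tasks are scored, each with a rank-based and a
calibration-based metric:

* **where** substitutions happen — *overlap* between the observed and
  expected per-IMGT-position substitution count distributions, and
  *R-precision*, the fraction of a PCP's k observed substitution sites found
  among the model's top-k site substitution probabilities (SSPs);
* **what** the outcome is — *substitution accuracy*, the fraction of
  substitution events whose observed amino acid attains the maximum
  conditional substitution probability (CSP), and *CSP perplexity*, the
  geometric mean of inverse CSPs of observed outcomes (1 is perfect).

All random tie-breaking flows from a single dataset-level seed recorded in
the report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._codons import AA_INDEX, AA_LETTERS
from .engines import CodonSiteDistribution
from .pcp_io import PCP, RegionScheme, UNASSIGNED

__all__ = [
    "SubstitutionEvent",
    "MetricsReport",
    "site_substitution_probability",
    "conditional_substitution_probability",
    "overlap",
    "r_precision",
    "substitution_accuracy",
    "csp_perplexity",
    "counts_distributions",
    "collect_events",
    "binned_ssp_distribution",
    "conserved_site_percentiles",
    "compute_metrics",
]

#: Floor for zero-probability observed outcomes in perplexity.
CSP_FLOOR = 1e-10


@dataclass(frozen=True)
class SubstitutionEvent:
    """One observed amino-acid substitution with the model's CSP vector at
    that site."""

    pcp_id: str
    site: int
    imgt_label: str
    region: str
    parent_aa: str
    child_aa: str
    csp: np.ndarray  # (20,), zero at wildtype, sums to 1


def site_substitution_probability(dist: CodonSiteDistribution) -> np.ndarray:
    """SSP per codon site: the probability of any amino-acid change,
    1 - P(wildtype). NaN at skipped sites."""
    ssp = np.full(dist.n_sites, np.nan)
    valid = dist.valid_mask()
    rows = np.flatnonzero(valid)
    ssp[rows] = 1.0 - dist.probs[rows, dist.parent_aa_idx[rows]]
    return ssp


def conditional_substitution_probability(dist: CodonSiteDistribution) -> np.ndarray:
    """CSP per codon site: distribution over the 19 non-wildtype amino acids
    conditioned on a substitution (returned as a 20-vector with zero at the
    wildtype). Rows with SSP = 0 are NaN and excluded from CSP metrics."""
    csp = np.full((dist.n_sites, 20), np.nan)
    ssp = site_substitution_probability(dist)
    undefined = 0
    for r in np.flatnonzero(dist.valid_mask()):
        if ssp[r] <= 0:
            undefined += 1
            continue
        row = dist.probs[r].copy()
        row[dist.parent_aa_idx[r]] = 0.0
        csp[r] = row / row.sum()
    if undefined:
        warnings.warn(f"{undefined} site(s) with SSP=0 excluded from CSP", stacklevel=2)
    return csp


def overlap(O: pd.Series, E: pd.Series) -> float:
    """Ratio of the area of intersection of two counts distributions to
    their average area: sum_i min(O_i, E_i) / sum_i (O_i + E_i)/2."""
    idx = O.index.union(E.index)
    o = O.reindex(idx, fill_value=0.0).to_numpy(dtype=float)
    e = E.reindex(idx, fill_value=0.0).to_numpy(dtype=float)
    denom = (o + e).sum() / 2.0
    if denom == 0:
        raise ValueError("overlap is undefined for two all-zero distributions")
    return float(np.minimum(o, e).sum() / denom)


def r_precision(
    ssp: np.ndarray, observed_sites: Iterable[int], rng: np.random.Generator
) -> float:
    """Fraction of the k observed substitution sites among the model's top-k
    SSP sites; sites tied at the k-th rank are chosen at random.

    NaN SSP entries (skipped sites) are ignored.
    """
    observed = set(int(s) for s in observed_sites)
    k = len(observed)
    if k < 1:
        raise ValueError("R-precision requires at least one observed substitution")
    valid = np.flatnonzero(~np.isnan(ssp))
    if k > valid.size:
        raise ValueError(f"k={k} exceeds the {valid.size} scored sites")
    vals = ssp[valid]
    order = np.argsort(-vals, kind="stable")
    kth_val = vals[order[k - 1]]
    above = valid[vals > kth_val]
    tied = valid[vals == kth_val]
    n_fill = k - above.size
    if n_fill < tied.size:
        fill = rng.choice(tied, size=n_fill, replace=False)
    else:
        fill = tied
    top_k = set(above.tolist()) | set(int(s) for s in fill)
    return len(top_k & observed) / k


def substitution_accuracy(
    events: Sequence[SubstitutionEvent], rng: np.random.Generator
) -> float:
    """Fraction of substitution events whose observed amino acid attains the
    maximum CSP at its site; argmax ties are broken at random. All events
    count equally regardless of PCP."""
    if not events:
        raise ValueError("substitution accuracy requires at least one event")
    hits = 0
    for ev in events:
        top = np.flatnonzero(ev.csp == ev.csp.max())
        pick = int(top[0]) if top.size == 1 else int(rng.choice(top))
        if AA_LETTERS[pick] == ev.child_aa:
            hits += 1
    return hits / len(events)


def csp_perplexity(events: Sequence[SubstitutionEvent]) -> float:
    """Geometric mean of inverse CSPs of the observed outcomes, computed in
    log space; zero-probability outcomes contribute a floor and a warning."""
    if not events:
        raise ValueError("CSP perplexity requires at least one event")
    logs = []
    floored = 0
    for ev in events:
        p = float(ev.csp[AA_INDEX[ev.child_aa]])
        if p <= 0:
            floored += 1
            p = CSP_FLOOR
        logs.append(np.log(p))
    if floored:
        warnings.warn(
            f"{floored} event(s) with zero CSP floored at {CSP_FLOOR}", stacklevel=2
        )
    return float(np.exp(-np.mean(logs)))


# ---------------------------------------------------------------------------
# Aggregation over a dataset

def counts_distributions(
    pcps: Sequence[PCP], ssps: Sequence[np.ndarray]
) -> tuple[pd.Series, pd.Series]:
    """Observed and expected substitution counts per IMGT position.

    O_i tallies observed amino-acid substitutions across PCPs at position i;
    E_i sums the SSPs. Their totals are the observed and expected numbers of
    substitutions in the dataset. Sites with undefined SSP are excluded from
    both.
    """
    O: dict[str, float] = {}
    E: dict[str, float] = {}
    for pcp, ssp in zip(pcps, ssps):
        labels = pcp.effective_position_map()
        observed = {r for r, _, _ in pcp.aa_substitutions()}
        for r, lbl in enumerate(labels):
            if np.isnan(ssp[r]):
                continue
            E[lbl] = E.get(lbl, 0.0) + float(ssp[r])
            if r in observed:
                O[lbl] = O.get(lbl, 0.0) + 1.0
    idx = sorted(set(O) | set(E), key=_imgt_sort_key)
    return (
        pd.Series([O.get(i, 0.0) for i in idx], index=idx, name="observed"),
        pd.Series([E.get(i, 0.0) for i in idx], index=idx, name="expected"),
    )


def _imgt_sort_key(label: str):
    try:
        return (0, float(label), "")
    except ValueError:
        return (1, 0.0, label)


def collect_events(
    pcp: PCP, dist: CodonSiteDistribution, scheme: RegionScheme | None = None
) -> list[SubstitutionEvent]:
    """Substitution events of one PCP with the model's CSP at each site."""
    scheme = scheme or RegionScheme()
    labels = pcp.effective_position_map()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        csp = conditional_substitution_probability(dist)
    out = []
    for r, parent, child in pcp.aa_substitutions():
        if np.isnan(csp[r]).any():
            continue
        out.append(
            SubstitutionEvent(
                pcp_id=pcp.pcp_id,
                site=r,
                imgt_label=labels[r],
                region=scheme.region_of(labels[r]),
                parent_aa=parent,
                child_aa=child,
                csp=csp[r],
            )
        )
    return out


def binned_ssp_distribution(
    ssps: Sequence[np.ndarray],
    observed_flags: Sequence[np.ndarray],
    bin_edges: Sequence[float] = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0),
) -> pd.DataFrame:
    """Observed vs expected substitution counts in bins of SSP value.

    Per bin, observed is the number of substituted sites whose SSP falls in
    the bin and expected is the sum of SSPs over all sites in the bin; over
    all bins the expected column sums to the total expected substitutions.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges[0] > 0 or edges[-1] < 1:
        raise ValueError("bin edges must cover [0, 1]")
    all_ssp = np.concatenate([np.asarray(s, float) for s in ssps])
    all_obs = np.concatenate([np.asarray(f, bool) for f in observed_flags])
    keep = ~np.isnan(all_ssp)
    all_ssp, all_obs = all_ssp[keep], all_obs[keep]
    which = np.clip(np.digitize(all_ssp, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        in_bin = which == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "observed": int(all_obs[in_bin].sum()),
                "expected": float(all_ssp[in_bin].sum()),
                "n_sites": int(in_bin.sum()),
            }
        )
    return pd.DataFrame(rows)


def conserved_site_percentiles(
    counts: pd.Series, sites: Sequence[str]
) -> dict[str, float]:
    """Percentile rank of named IMGT positions' substitution counts among all
    positions (strictly-smaller fraction, midpoint adjustment for ties)."""
    vals = counts.to_numpy(dtype=float)
    n = vals.size
    out = {}
    for site in sites:
        if site not in counts.index:
            raise KeyError(f"IMGT position {site!r} not in the counts distribution")
        c = float(counts.loc[site])
        smaller = float((vals < c).sum())
        ties = float((vals == c).sum())
        out[site] = 100.0 * (smaller + (ties - 1) / 2.0) / n
    return out


# ---------------------------------------------------------------------------
# Report

@dataclass
class MetricsReport:
    """The four metrics, overall and stratified, for one model on one
    dataset."""

    model_name: str
    seed: int
    n_pcps: int
    n_events: int
    overall: dict[str, float] = field(default_factory=dict)
    by_region: dict[str, dict[str, float]] = field(default_factory=dict)
    by_k: dict[int, dict[str, float]] = field(default_factory=dict)
    ssp_bins: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "model": self.model_name,
            "seed": self.seed,
            "n_pcps": self.n_pcps,
            "n_events": self.n_events,
            "overall": self.overall,
            "by_region": self.by_region,
            "by_k": {str(k): v for k, v in sorted(self.by_k.items())},
            "by_ssp_bin": self.ssp_bins,
        }
        return json.dumps(payload, indent=2)


def _metric_block(
    pcps: Sequence[PCP],
    ssps: Sequence[np.ndarray],
    events: Sequence[SubstitutionEvent],
    rng: np.random.Generator,
    site_filter=None,
) -> dict[str, float]:
    """The four metrics over a (possibly region-restricted) slice.

    ``site_filter(pcp) -> boolean site mask`` restricts SSP sites; events are
    assumed pre-filtered to the same slice.
    """
    out: dict[str, float] = {}
    O_parts, E_parts, rprecs = [], [], []
    for pcp, ssp in zip(pcps, ssps):
        if site_filter is not None:
            ssp = ssp.copy()
            ssp[~site_filter(pcp)] = np.nan
        observed = [
            r for r, _, _ in pcp.aa_substitutions() if not np.isnan(ssp[r])
        ]
        if observed:
            rprecs.append(r_precision(ssp, observed, rng))
        O_parts.append(pcp)
        E_parts.append(ssp)
    O, E = counts_distributions(O_parts, E_parts)
    if len(O) and (O.sum() + E.sum()) > 0:
        out["overlap"] = overlap(O, E)
    if rprecs:
        out["r_precision"] = float(np.mean(rprecs))
    if events:
        out["substitution_accuracy"] = substitution_accuracy(events, rng)
        out["csp_perplexity"] = csp_perplexity(events)
    out["n_events"] = len(events)
    return out


def compute_metrics(
    pcps: Sequence[PCP],
    dists: Sequence[CodonSiteDistribution],
    model_name: str = "model",
    scheme: RegionScheme | None = None,
    seed: int = 0,
    ssp_bin_edges: Sequence[float] = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0),
) -> MetricsReport:
    """Compute the full metrics report for one model's distributions, overall
    plus per-region and per-substitutions-per-PCP strata."""
    scheme = scheme or RegionScheme()
    rng = np.random.default_rng(seed)
    ssps = [site_substitution_probability(d) for d in dists]
    events = [ev for pcp, d in zip(pcps, dists) for ev in collect_events(pcp, d, scheme)]

    report = MetricsReport(
        model_name=model_name,
        seed=seed,
        n_pcps=len(pcps),
        n_events=len(events),
    )
    report.overall = _metric_block(pcps, ssps, events, rng)

    region_names = list(scheme.region_bounds) + [UNASSIGNED]
    region_masks = {
        id(pcp): np.array([scheme.region_of(l) for l in pcp.effective_position_map()])
        for pcp in pcps
    }
    for region in region_names:
        region_events = [ev for ev in events if ev.region == region]
        block = _metric_block(
            pcps,
            ssps,
            region_events,
            rng,
            site_filter=lambda p, _r=region: region_masks[id(p)] == _r,
        )
        if block.get("n_events") or "overlap" in block:
            report.by_region[region] = block

    k_of = [len(p.aa_substitutions()) for p in pcps]
    for k in sorted(set(k_of)):
        sel = [i for i, kk in enumerate(k_of) if kk == k]
        sub_pcps = [pcps[i] for i in sel]
        ids = {pcps[i].pcp_id for i in sel}
        sub_events = [ev for ev in events if ev.pcp_id in ids]
        report.by_k[k] = _metric_block(
            sub_pcps, [ssps[i] for i in sel], sub_events, rng
        )

    observed_flags = []
    for pcp, ssp in zip(pcps, ssps):
        flags = np.zeros(len(ssp), dtype=bool)
        for r, _, _ in pcp.aa_substitutions():
            flags[r] = True
        observed_flags.append(flags)
    report.ssp_bins = binned_ssp_distribution(ssps, observed_flags, ssp_bin_edges).to_dict(
        "records"
    )
    return report
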