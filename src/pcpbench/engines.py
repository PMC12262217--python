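"""Per-codon-site amino-acid substitution probabilities under the three
evaluation frameworks, with per-PCP branch-length optimization.

The mutation process is a single-hit approximation: each nucleotide site
waits an exponential time with rate ``lambda_i`` for its (at most one)
mutation over the branch, so after time tau the site is unchanged with
probability ``exp(-lambda_i * tau)`` and has mutated to base x with
probability ``(1 - exp(-lambda_i * tau)) * p_{i,x}``. Codon outcome
probabilities are products of the three per-site terms; stop-codon outcomes
are excluded and the 61 sense outcomes renormalized (conditioning on a
non-stop outcome, since stop-containing sequences are filtered out).

Selection enters as a multiplicative factor F = 2/(1 + 1/R) on every
non-wildtype codon outcome, where R is the preference ratio of the outcome
amino acid over the parent amino acid. F is bounded in (0, 2) so that a
single outcome's probability can at most double; in the rare case a modified
probability still exceeds 1 it is clamped, and if the non-wildtype mass
exceeds 1 it is renormalized with the no-change probability set to 0.

Amino-acid (language-model) frameworks have no rate structure: their
per-site probabilities are scaled by the mutability ``1 - exp(-tau)`` with
the remainder assigned to the wildtype residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

from ._codons import (
    AA_INDEX,
    BASE_INDEX,
    CODON_AA_IDX,
    CODON_AA_MATRIX,
    CODON_BASE_IDX,
    CODON_INDEX,
    IS_STOP,
)
from .models import NTSiteRates
from .pcp_io import PCP

__all__ = [
    "BranchFit",
    "CodonSiteDistribution",
    "SelectionProfile",
    "selection_factor",
    "site_mutation_probs",
    "codon_outcome_probs",
    "codon_aa_distribution",
    "apply_selection",
    "nt_log_likelihood",
    "ntaa_log_likelihood",
    "aa_scaled_distribution",
    "aa_log_likelihood",
    "optimize_branch_length",
    "fit_branch_nt",
    "fit_branch_ntaa",
    "fit_branch_aa",
    "parent_codon_indices",
]

#: Branch-length search interval (log-space bounded scalar maximization).
TAU_BOUNDS = (1e-9, 10.0)
#: Convergence tolerance on log(tau).
TAU_XATOL = 1e-8
#: Floor under probabilities before taking logs, so a zero-probability
#: observed outcome yields a large negative contribution instead of -inf.
LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class BranchFit:
    """Result of maximum-likelihood branch-length optimization for one PCP."""

    tau_hat: float
    log_likelihood: float
    n_evals: int
    init_tau: float


@dataclass
class CodonSiteDistribution:
    """Per codon site, a probability vector over the 20 amino acids
    (wildtype included). Rows of skipped sites (ambiguous codons) are NaN."""

    probs: np.ndarray          # (n_codons, 20)
    parent_aa_idx: np.ndarray  # (n_codons,), -1 where skipped

    @property
    def n_sites(self) -> int:
        return self.probs.shape[0]

    def valid_mask(self) -> np.ndarray:
        return self.parent_aa_idx >= 0


@dataclass
class SelectionProfile:
    """Per codon site x amino acid: preference ratio R > 0 and the bounded
    selection factor F = 2/(1 + 1/R) in (0, 2), with F(1) = 1."""

    ratios: np.ndarray   # (n_sites, 20)
    factors: np.ndarray  # (n_sites, 20)

    @classmethod
    def from_ratios(cls, R: np.ndarray) -> "SelectionProfile":
        R = np.asarray(R, dtype=float)
        if np.any(R <= 0):
            raise ValueError("preference ratios must be positive")
        return cls(ratios=R, factors=selection_factor(R))


def selection_factor(R: np.ndarray | float) -> np.ndarray | float:
    """Map a preference ratio R in (0, inf) to the bounded multiplicative
    selection factor F = 2/(1 + 1/R): increasing, F(1) = 1, limits 0 and 2."""
    R = np.asarray(R, dtype=float)
    out = 2.0 / (1.0 + 1.0 / R)
    return out if out.ndim else float(out)


def site_mutation_probs(rates: NTSiteRates, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-site mutation probabilities after time tau.

    Returns ``(P, stay)`` where ``P[i, x] = (1 - exp(-lam_i tau)) p_{i,x}``
    and ``stay[i] = exp(-lam_i tau)``; per site, ``stay + sum_x P = 1``.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    stay = np.exp(-rates.lam * tau)
    P = (1.0 - stay)[:, None] * rates.cond_probs
    return P, stay


def parent_codon_indices(parent_nt: str) -> np.ndarray:
    """Codon index (0..63) per codon site; -1 for codons containing n."""
    parent_nt = parent_nt.lower()
    n_codons = len(parent_nt) // 3
    idx = np.empty(n_codons, dtype=np.intp)
    for r in range(n_codons):
        codon = parent_nt[3 * r : 3 * r + 3]
        idx[r] = CODON_INDEX.get(codon, -1)
    return idx


def _site_term_tensor(P: np.ndarray, stay: np.ndarray, codon_idx: np.ndarray) -> np.ndarray:
    """(n_valid, 3, 4) tensor T[r, j, b]: probability that position j of valid
    codon r ends as base b (stay at the parent base, mutate elsewhere)."""
    n = codon_idx.size
    sites = 3 * np.flatnonzero(codon_idx >= 0)[:, None] + np.arange(3)
    T = P[sites]  # (n_valid, 3, 4) -- wait, shape fixed below
    valid = codon_idx[codon_idx >= 0]
    pb = CODON_BASE_IDX[valid]  # (n_valid, 3) parent base index
    rows = np.arange(sites.shape[0])[:, None]
    cols = np.arange(3)[None, :]
    T[rows, cols, pb] = stay[sites]
    return T


def codon_outcome_probs(
    rates: NTSiteRates,
    parent_nt: str,
    tau: float,
    factors: np.ndarray | None = None,
    events: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution over the 64 codon outcomes at every codon site.

    This is the single code path shared by the neutral (NT) and selection
    (NT-AA) frameworks, the likelihoods, and the simulator. ``factors``,
    if given, is the (n_codons, 20) selection-factor table F applied to
    every non-wildtype outcome. Stop outcomes are excluded and rows
    renormalized over the 61 sense codons.

    Returns ``(probs64, codon_idx)`` where ``probs64`` is (n_codons, 64)
    with NaN rows at codon sites containing n, and ``codon_idx`` the parent
    codon index per site (-1 where skipped).

    ``events``, if supplied, accumulates counts under the keys ``"clamped"``
    (individual outcome probabilities clamped at 1) and ``"renormalized"``
    (sites whose non-wildtype mass exceeded 1).
    """
    codon_idx = parent_codon_indices(parent_nt)
    valid = codon_idx >= 0
    if np.any(IS_STOP[codon_idx[valid]]):
        raise ValueError("parent sequence contains a stop codon")
    if factors is not None:
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (codon_idx.size, 20):
            raise ValueError("selection factors must be (n_codons, 20)")
        fv = factors[valid]
        if np.any(fv <= 0) or np.any(fv >= 2):
            raise ValueError("selection factors must lie strictly in (0, 2)")

    P, stay = site_mutation_probs(rates, tau)
    T = _site_term_tensor(P, stay, codon_idx)
    p64 = (
        T[:, 0, CODON_BASE_IDX[:, 0]]
        * T[:, 1, CODON_BASE_IDX[:, 1]]
        * T[:, 2, CODON_BASE_IDX[:, 2]]
    )  # (n_valid, 64)

    vidx = codon_idx[valid]
    rows = np.arange(vidx.size)
    nonwt = p64
    nonwt[rows, vidx] = 0.0

    if factors is not None:
        # F per outcome codon via its amino acid; stops get 1 (removed later)
        f64 = factors[valid][:, np.clip(CODON_AA_IDX, 0, None)]
        f64[:, IS_STOP] = 1.0
        nonwt = nonwt * f64
        over_one = nonwt > 1.0
        if over_one.any():
            if events is not None:
                events["clamped"] = events.get("clamped", 0) + int(over_one.sum())
            np.minimum(nonwt, 1.0, out=nonwt)

    s = nonwt.sum(axis=1)
    over = s > 1.0
    if over.any():
        if events is not None:
            events["renormalized"] = events.get("renormalized", 0) + int(over.sum())
        nonwt[over] /= s[over, None]
    wt = np.where(over, 0.0, 1.0 - s)
    nonwt[rows, vidx] = wt

    # condition on a non-stop outcome
    nonwt[:, IS_STOP] = 0.0
    nonwt /= nonwt.sum(axis=1, keepdims=True)

    out = np.full((codon_idx.size, 64), np.nan)
    out[valid] = nonwt
    return out, codon_idx


def _aa_from_codon_probs(probs64: np.ndarray, codon_idx: np.ndarray) -> CodonSiteDistribution:
    aa = np.full((codon_idx.size, 20), np.nan)
    valid = codon_idx >= 0
    aa[valid] = probs64[valid] @ CODON_AA_MATRIX
    parent_aa_idx = np.where(valid, CODON_AA_IDX[np.clip(codon_idx, 0, None)], -1)
    return CodonSiteDistribution(probs=aa, parent_aa_idx=parent_aa_idx)


def codon_aa_distribution(
    rates: NTSiteRates, parent_nt: str, tau: float
) -> CodonSiteDistribution:
    """Neutral (NT framework) amino-acid distribution per codon site: codon
    outcome probabilities aggregated over the sense codons of each amino
    acid, with the wildtype amino acid accumulating its synonymous-codon
    mass plus the no-change term."""
    probs64, codon_idx = codon_outcome_probs(rates, parent_nt, tau)
    return _aa_from_codon_probs(probs64, codon_idx)


def apply_selection(
    rates: NTSiteRates,
    parent_nt: str,
    profile: SelectionProfile,
    tau: float,
    events: dict | None = None,
) -> CodonSiteDistribution:
    """NT-AA framework amino-acid distribution: the neutral codon outcome
    probabilities modified by the selection factors of their amino acids."""
    probs64, codon_idx = codon_outcome_probs(
        rates, parent_nt, tau, factors=profile.factors, events=events
    )
    return _aa_from_codon_probs(probs64, codon_idx)


# ---------------------------------------------------------------------------
# Likelihoods

def _codon_site_mask(pcp: PCP) -> np.ndarray:
    return np.array(pcp.codon_site_mask(), dtype=bool)


def nt_log_likelihood(pcp: PCP, rates: NTSiteRates, tau: float) -> float:
    """Nucleotide-level log-likelihood of the child: per site, the stay
    probability where child equals parent and the mutation probability to
    the observed base elsewhere. Sites in n-containing codons are skipped."""
    P, stay = site_mutation_probs(rates, tau)
    mask = np.repeat(_codon_site_mask(pcp), 3)
    ll = 0.0
    for i in np.flatnonzero(mask):
        p, c = pcp.parent_nt[i], pcp.child_nt[i]
        term = stay[i] if c == p else P[i, BASE_INDEX[c]]
        ll += np.log(max(term, LOG_FLOOR))
    return float(ll)


def ntaa_log_likelihood(
    pcp: PCP,
    rates: NTSiteRates,
    profile: SelectionProfile | None,
    tau: float,
    events: dict | None = None,
) -> float:
    """Codon-level log-likelihood of the child under the selection-modified
    (or neutral, if ``profile`` is None) codon outcome distribution."""
    factors = profile.factors if profile is not None else None
    probs64, codon_idx = codon_outcome_probs(
        rates, pcp.parent_nt, tau, factors=factors, events=events
    )
    child_idx = parent_codon_indices(pcp.child_nt)
    ll = 0.0
    zero_hits = 0
    for r in range(codon_idx.size):
        if codon_idx[r] < 0 or child_idx[r] < 0:
            continue
        p = probs64[r, child_idx[r]]
        if p <= 0:
            zero_hits += 1
        ll += np.log(max(p, LOG_FLOOR))
    if zero_hits:
        warnings.warn(
            f"pcp {pcp.pcp_id!r}: {zero_hits} child codon(s) with zero probability",
            stacklevel=2,
        )
    return float(ll)


def aa_scaled_distribution(
    site_probs: np.ndarray, parent_aa: str, tau: float
) -> CodonSiteDistribution:
    """Scale parent-sequence amino-acid probabilities (e.g. language-model
    softmax output) by the mutability 1 - exp(-tau).

    The wildtype residue receives ``exp(-tau) + (1 - exp(-tau)) P_wt`` and
    every other amino acid ``(1 - exp(-tau)) P``; rows still sum to 1, and
    the ranking of non-wildtype amino acids is unchanged for every tau.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    site_probs = np.asarray(site_probs, dtype=float)
    if site_probs.shape != (len(parent_aa), 20):
        raise ValueError("site_probs must be (n_sites, 20) matching the parent")
    mut = 1.0 - np.exp(-tau)
    scaled = mut * site_probs
    parent_idx = np.array([AA_INDEX.get(a, -1) for a in parent_aa])
    valid = parent_idx >= 0
    rows = np.flatnonzero(valid)
    scaled[rows, parent_idx[rows]] += np.exp(-tau)
    scaled[~valid] = np.nan
    return CodonSiteDistribution(probs=scaled, parent_aa_idx=parent_idx)


def aa_log_likelihood(pcp: PCP, site_probs: np.ndarray, tau: float) -> float:
    """Log-likelihood of the child amino-acid sequence under the scaled
    language-model distribution; ambiguous sites are skipped."""
    dist = aa_scaled_distribution(site_probs, pcp.parent_aa, tau)
    mask = _codon_site_mask(pcp)
    ll = 0.0
    zero_hits = 0
    for r, child in enumerate(pcp.child_aa):
        if not mask[r] or dist.parent_aa_idx[r] < 0 or child not in AA_INDEX:
            continue
        p = dist.probs[r, AA_INDEX[child]]
        if p <= 0:
            zero_hits += 1
        ll += np.log(max(p, LOG_FLOOR))
    if zero_hits:
        warnings.warn(
            f"pcp {pcp.pcp_id!r}: {zero_hits} child residue(s) with zero probability",
            stacklevel=2,
        )
    return float(ll)


# ---------------------------------------------------------------------------
# Branch-length optimization

def optimize_branch_length(
    loglik: Callable[[float], float],
    init: float,
    bounds: tuple[float, float] = TAU_BOUNDS,
) -> BranchFit:
    """Maximize a log-likelihood over the branch length tau.

    Deterministic bounded scalar maximization over log(tau); ``init`` is the
    normalized nucleotide mutation frequency of the PCP and serves as a
    guaranteed-no-worse fallback.
    """
    lo, hi = bounds
    n_evals = 0

    def neg(log_tau: float) -> float:
        nonlocal n_evals
        n_evals += 1
        val = loglik(float(np.exp(log_tau)))
        if np.isnan(val):
            raise ValueError("log-likelihood returned NaN during optimization")
        return -val

    res = minimize_scalar(
        neg,
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": TAU_XATOL},
    )
    tau_hat = float(np.exp(res.x))
    ll_hat = -float(res.fun)
    if not np.isfinite(ll_hat):
        raise ValueError("log-likelihood is non-finite over the search interval")
    init_clipped = float(np.clip(init, lo, hi))
    ll_init = loglik(init_clipped)
    n_evals += 1
    if ll_init > ll_hat:
        tau_hat, ll_hat = init_clipped, float(ll_init)
    return BranchFit(
        tau_hat=tau_hat, log_likelihood=ll_hat, n_evals=n_evals, init_tau=init_clipped
    )


def _init_tau(pcp: PCP) -> float:
    return pcp.nt_mutation_count() / len(pcp.parent_nt)


def fit_branch_nt(pcp: PCP, rates: NTSiteRates) -> BranchFit:
    """Fit tau for an NT-framework model by the nucleotide-level likelihood.

    The per-site terms are precomputed so each evaluation is a vectorized
    function of tau alone.
    """
    mask = np.repeat(_codon_site_mask(pcp), 3)
    par = np.array([BASE_INDEX.get(b, -1) for b in pcp.parent_nt])
    chi = np.array([BASE_INDEX.get(b, -1) for b in pcp.child_nt])
    use = mask & (par >= 0) & (chi >= 0)
    same = use & (par == chi)
    diff = use & (par != chi)
    lam_same = rates.lam[same]
    lam_diff = rates.lam[diff]
    p_diff = rates.cond_probs[np.flatnonzero(diff), chi[diff]]
    log_p_diff = np.log(np.maximum(p_diff, LOG_FLOOR))

    def loglik(tau: float) -> float:
        ll = -tau * lam_same.sum()
        ll += np.sum(np.log(np.maximum(1.0 - np.exp(-lam_diff * tau), LOG_FLOOR)))
        ll += log_p_diff.sum()
        return float(ll)

    return optimize_branch_length(loglik, _init_tau(pcp))


def fit_branch_ntaa(
    pcp: PCP,
    rates: NTSiteRates,
    profile: SelectionProfile | None,
    events: dict | None = None,
) -> BranchFit:
    """Fit tau for an NT-AA-framework model by the codon-level likelihood."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = optimize_branch_length(
            lambda tau: ntaa_log_likelihood(pcp, rates, profile, tau, events=events),
            _init_tau(pcp),
        )
    return fit


def fit_branch_aa(pcp: PCP, site_probs: np.ndarray) -> BranchFit:
    """Fit tau for an AA-framework model by the amino-acid likelihood."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = optimize_branch_length(
            lambda tau: aa_log_likelihood(pcp, site_probs, tau), _init_tau(pcp)
        )
    return fit
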