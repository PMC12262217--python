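import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcpbench import engines
from pcpbench._codons import AA_INDEX, CODON_INDEX
from pcpbench.engines import (
    SelectionProfile,
    aa_log_likelihood,
    aa_scaled_distribution,
    apply_selection,
    codon_aa_distribution,
    fit_branch_nt,
    nt_log_likelihood,
    ntaa_log_likelihood,
    optimize_branch_length,
    selection_factor,
    site_mutation_probs,
)
from pcpbench.models import NTSiteRates
from pcpbench.pcp_io import PCP

from conftest import brute_force_codon_aa, make_random_rates, uniform_rates


class TestSiteMutationProbs:
    def test_small_tau_limit(self):
        rates = uniform_rates("acg")
        P, stay = site_mutation_probs(rates, 1e-12)
        assert np.allclose(stay, 1.0)
        assert np.allclose(P, 0.0, atol=1e-12)

    def test_large_tau_recovers_conditional_probs(self):
        rates = uniform_rates("acg", lam=1.0)
        P, stay = site_mutation_probs(rates, 50.0)
        assert np.allclose(stay, 0.0, atol=1e-20)
        assert np.allclose(P, rates.cond_probs)

    def test_half_life_value(self):
        # lam=1, tau=ln 2, p_c=0.5 -> P_c = (1 - 1/2) * 0.5 = 0.25
        cp = np.array([[0.0, 0.5, 0.5, 0.0]])
        rates = NTSiteRates(lam=np.array([1.0]), cond_probs=cp)
        P, stay = site_mutation_probs(rates, np.log(2.0))
        assert P[0, 1] == pytest.approx(0.25)
        assert stay[0] + P.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("tau", [0.0, -1.0])
    def test_nonpositive_tau_rejected(self, tau):
        with pytest.raises(ValueError, match="positive"):
            site_mutation_probs(uniform_rates("acg"), tau)


class TestCodonAADistribution:
    def test_cysteine_mass_from_glycine_codon(self, rng):
        # parent ggt: cysteine is reached via tgt (one hit) and tgc (two hits)
        rates = make_random_rates("ggt", rng)
        tau = 0.2
        P, stay = site_mutation_probs(rates, tau)
        p_tgt = P[0, 3] * stay[1] * stay[2]
        p_tgc = P[0, 3] * stay[1] * P[2, 1]
        # normalizing constant: total sense-outcome mass
        sense = sum(
            v for k, v in brute_force_codon_aa("ggt", P, stay).items()
        )
        assert sense == pytest.approx(1.0)
        dist = codon_aa_distribution(rates, "ggt", tau)
        oracle = brute_force_codon_aa("ggt", P, stay)
        assert dist.probs[0, AA_INDEX["C"]] == pytest.approx(oracle["C"], abs=1e-12)
        assert oracle["C"] >= p_tgt + p_tgc  # pre-normalization lower bound

    def test_tau_to_zero_gives_wildtype(self):
        rates = uniform_rates("ggtacc")
        dist = codon_aa_distribution(rates, "ggtacc", 1e-12)
        assert dist.probs[0, AA_INDEX["G"]] == pytest.approx(1.0)
        assert dist.probs[1, AA_INDEX["T"]] == pytest.approx(1.0)

    def test_matches_brute_force_on_random_draws(self, rng):
        for _ in range(50):
            parent = "ggt" if rng.random() < 0.1 else None
            while parent is None:
                cand = "".join(rng.choice(list("acgt"), 3))
                if CODON_INDEX[cand] >= 0 and cand not in ("taa", "tag", "tga"):
                    parent = cand
            rates = make_random_rates(parent, rng)
            tau = float(rng.uniform(0.01, 2.0))
            P, stay = site_mutation_probs(rates, tau)
            oracle = brute_force_codon_aa(parent, P, stay)
            dist = codon_aa_distribution(rates, parent, tau)
            for aa, idx in AA_INDEX.items():
                assert dist.probs[0, idx] == pytest.approx(
                    oracle.get(aa, 0.0), abs=1e-9
                )

    def test_stop_parent_rejected(self):
        rates = uniform_rates("taa")
        with pytest.raises(ValueError, match="stop"):
            codon_aa_distribution(rates, "taa", 0.1)

    def test_n_codon_sites_are_skipped(self):
        rates = uniform_rates("ggtnnn")
        dist = codon_aa_distribution(rates, "ggtnnn", 0.1)
        assert np.isnan(dist.probs[1]).all()
        assert dist.parent_aa_idx[1] == -1


class TestNTLogLikelihood:
    def test_identical_child_is_sum_of_stay_terms(self):
        parent = "acgtgc"
        rates = uniform_rates(parent, lam=0.7)
        tau = 0.31
        ll = nt_log_likelihood(PCP("x", "f", parent, parent), rates, tau)
        assert ll == pytest.approx(-0.7 * tau * 6)

    def test_single_mutation_hand_expansion(self):
        parent, child = "acgtgc", "ccgtgc"
        rates = uniform_rates(parent, lam=1.0)
        tau = 0.4
        expected = np.log((1 - np.exp(-tau)) / 3.0) - 5 * tau
        ll = nt_log_likelihood(PCP("x", "f", parent, child), rates, tau)
        assert ll == pytest.approx(expected)

    def test_monotone_decreasing_for_identical_pair(self):
        parent = "acgtgc"
        rates = uniform_rates(parent)
        pcp = PCP("x", "f", parent, parent)
        lls = [nt_log_likelihood(pcp, rates, t) for t in (0.01, 0.1, 1.0)]
        assert lls[0] > lls[1] > lls[2]


class TestOptimizeBranchLength:
    @pytest.mark.parametrize("n,m,lam", [(30, 3, 1.0), (300, 30, 0.5), (90, 1, 2.0)])
    def test_matches_closed_form_mle(self, n, m, lam):
        parent = "aca" * (n // 3)
        child = list(parent)
        flip = {"a": "c", "c": "g"}
        for i in range(m):
            child[3 * i] = flip[parent[3 * i]]
        pcp = PCP("x", "f", parent, "".join(child))
        fit = fit_branch_nt(pcp, uniform_rates(parent, lam=lam))
        closed = -np.log(1.0 - m / n) / lam
        assert abs(fit.tau_hat - closed) / closed < 1e-5
        assert fit.log_likelihood >= nt_log_likelihood(
            pcp, uniform_rates(parent, lam=lam), fit.init_tau
        ) - 1e-9

    def test_no_mutations_drives_tau_to_lower_bound(self):
        parent = "aca" * 10
        fit = fit_branch_nt(PCP("x", "f", parent, parent), uniform_rates(parent))
        assert fit.tau_hat <= 1.1e-9

    def test_concave_quadratic_in_log_tau(self):
        argmax = 0.05
        loglik = lambda tau: -((np.log(tau) - np.log(argmax)) ** 2)
        fit = optimize_branch_length(loglik, init=0.01)
        assert fit.tau_hat == pytest.approx(argmax, rel=1e-6)


class TestSelection:
    def test_selection_factor_contract(self):
        assert selection_factor(1.0) == 1.0
        grid = np.logspace(-6, 6, 41)
        F = selection_factor(grid)
        assert np.all(np.diff(F) > 0)
        assert np.all((F > 0) & (F < 2))

    def test_neutral_factors_reproduce_neutral_path(self, rng):
        parent = "ggtacctgc"
        rates = make_random_rates(parent, rng)
        tau = 0.23
        neutral = codon_aa_distribution(rates, parent, tau)
        profile = SelectionProfile.from_ratios(np.ones((3, 20)))
        selected = apply_selection(rates, parent, profile, tau)
        assert np.allclose(selected.probs, neutral.probs, atol=1e-12, equal_nan=True)

    def test_large_ratio_doubles_outcome_mass(self, rng):
        parent = "ggt"
        rates = make_random_rates(parent, rng)
        tau = 0.05  # small tau: no clamping, no renormalization
        R = np.ones((1, 20))
        R[0, AA_INDEX["C"]] = 1e12
        neutral = codon_aa_distribution(rates, parent, tau)
        selected = apply_selection(rates, parent, SelectionProfile.from_ratios(R), tau)
        # relative to the (unnormalized) neutral codon mass the factor is ~2;
        # compare through the ratio to another non-wildtype amino acid
        c, a = AA_INDEX["C"], AA_INDEX["A"]
        ratio = (selected.probs[0, c] / selected.probs[0, a]) / (
            neutral.probs[0, c] / neutral.probs[0, a]
        )
        assert ratio == pytest.approx(2.0, rel=1e-6)

    def test_renormalization_when_mass_exceeds_one(self):
        # huge rates: neutral non-wildtype mass near 1; F near 2 pushes it over
        parent = "ggt"
        rates = uniform_rates(parent, lam=100.0)
        R = np.full((1, 20), 1e9)
        events = {}
        dist = apply_selection(
            rates, parent, SelectionProfile.from_ratios(R), 1.0, events=events
        )
        wt = dist.probs[0, AA_INDEX["G"]]
        # no-change mass zeroed; only synonymous-codon mass can remain at wildtype
        assert events.get("renormalized", 0) >= 1
        assert dist.probs[0].sum() == pytest.approx(1.0)
        neutral = codon_aa_distribution(rates, parent, 1.0)
        assert wt < neutral.probs[0, AA_INDEX["G"]]

    def test_factor_outside_contract_rejected(self):
        parent = "ggt"
        rates = uniform_rates(parent)
        bad = SelectionProfile(ratios=np.ones((1, 20)), factors=np.full((1, 20), 2.5))
        with pytest.raises(ValueError, match="\\(0, 2\\)"):
            apply_selection(rates, parent, bad, 0.1)

    def test_ntaa_likelihood_prefers_selected_outcomes(self, rng):
        parent, child = "ggtacc", "tgtacc"  # G->C substitution at codon 0
        rates = make_random_rates(parent, rng)
        pcp = PCP("x", "f", parent, child)
        tau = 0.1
        R = np.ones((2, 20))
        R[0, AA_INDEX["C"]] = 50.0
        favored = ntaa_log_likelihood(pcp, rates, SelectionProfile.from_ratios(R), tau)
        neutral = ntaa_log_likelihood(pcp, rates, None, tau)
        assert favored > neutral

    def test_selection_toward_child_shrinks_tau_hat(self, rng):
        # sequence-wide preference for the observed outcome: boosting the
        # substitution at unchanged codons too means less evolutionary time
        # is needed to explain the one substitution that did happen
        parent, child = "ggtggt", "tgtggt"
        rates = make_random_rates(parent, rng)
        pcp = PCP("x", "f", parent, child)
        R = np.ones((2, 20))
        R[:, AA_INDEX["C"]] = 100.0
        fit_sel = engines.fit_branch_ntaa(pcp, rates, SelectionProfile.from_ratios(R))
        fit_neu = engines.fit_branch_ntaa(pcp, rates, None)
        assert fit_sel.tau_hat < fit_neu.tau_hat


class TestAAFramework:
    def test_uniform_scaling_at_half_life(self):
        probs = np.full((1, 20), 1.0 / 20.0)
        dist = aa_scaled_distribution(probs, "A", np.log(2.0))
        assert dist.probs[0, AA_INDEX["A"]] == pytest.approx(0.525)
        assert dist.probs[0, AA_INDEX["C"]] == pytest.approx(0.025)
        assert dist.probs[0].sum() == pytest.approx(1.0)

    def test_limits(self, rng):
        probs = rng.dirichlet(np.ones(20), size=3)
        tiny = aa_scaled_distribution(probs, "ACD", 1e-12)
        for r, aa in enumerate("ACD"):
            assert tiny.probs[r, AA_INDEX[aa]] == pytest.approx(1.0)
        huge = aa_scaled_distribution(probs, "ACD", 50.0)
        assert np.allclose(huge.probs, probs, atol=1e-9)

    def test_scaling_preserves_nonwildtype_argmax(self, rng):
        probs = rng.dirichlet(np.ones(20), size=5)
        parent = "ACDEF"
        ref = None
        for tau in (1e-6, 0.01, 0.3, 1.0, 10.0):
            dist = aa_scaled_distribution(probs, parent, tau)
            masked = dist.probs.copy()
            for r, aa in enumerate(parent):
                masked[r, AA_INDEX[aa]] = -1.0
            order = np.argmax(masked, axis=1)
            if ref is None:
                ref = order
            assert np.array_equal(order, ref)

    def test_identical_child_expansion(self):
        probs = np.full((2, 20), 1.0 / 20.0)
        pcp = PCP("x", "f", "gctgct", "gctgct")  # AA parent/child
        tau = 0.7
        expected = 2 * np.log(np.exp(-tau) + (1 - np.exp(-tau)) / 20.0)
        assert aa_log_likelihood(pcp, probs, tau) == pytest.approx(expected)

    def test_optimizer_matches_grid_search(self, rng):
        probs = rng.dirichlet(np.ones(20), size=4)
        pcp = PCP("x", "f", "gctaaatgtgac", "gcttgttgtgac")
        fit = engines.fit_branch_aa(pcp, probs)
        grid = np.exp(np.linspace(np.log(1e-6), np.log(10.0), 4000))
        lls = [aa_log_likelihood(pcp, probs, t) for t in grid]
        assert fit.log_likelihood >= max(lls) - 1e-6

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            aa_scaled_distribution(np.full((1, 20), 0.05), "A", 0.0)


@settings(max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    tau=st.floats(1e-4, 5.0),
    selected=st.booleans(),
)
def test_distribution_rows_always_sum_to_one(seed, tau, selected):
    """Every codon-site amino-acid distribution is a probability vector."""
    rng = np.random.default_rng(seed)
    from pcpbench.synthetic_data import random_parent

    parent = random_parent(30, rng)
    rates = make_random_rates(parent, rng)
    if selected:
        R = np.exp(rng.normal(0, 2, size=(10, 20)))
        dist = apply_selection(rates, parent, SelectionProfile.from_ratios(R), tau)
    else:
        dist = codon_aa_distribution(rates, parent, tau)
    assert np.allclose(dist.probs.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(dist.probs >= 0)
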