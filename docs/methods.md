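# Methods

## The substitution process

All three evaluation frameworks reduce a model to the same object: for each
codon site r of a parent sequence, a probability vector over the 20
amino-acid outcomes after branch length τ.

**Single-hit nucleotide process.** Nucleotide models assign each site i a
neutral rate λᵢ and a conditional target distribution pᵢ,ₓ with zero mass on
the wildtype base (the model describes what happens *given* a mutation; this
differs from the usual CTMC convention). With exponential waiting times, the
no-change probability after time τ is e^(−λᵢτ) and the probability of
observing non-wildtype base x is (1 − e^(−λᵢτ))·pᵢ,ₓ. We allow at most one
hit per nucleotide site per branch. This is an approximation — a site could
mutate twice — but BCR lineage branches are short (a few mutations per
sequence), so the expected number of mutations per site is far below one and
multi-hit paths contribute negligibly. A per-nucleotide Gillespie-style
simulator that allows multi-hits would be the natural extension for
quantifying the approximation error; it is deliberately not the default,
because the simulator is meant to be model-consistent with the evaluator
(see below).

**Codon aggregation.** The probability of a codon outcome is the product of
its three per-site terms (stay where the base matches the parent, mutate
otherwise). Stop-codon outcomes are excluded and the 61 sense outcomes
renormalized — sequences containing stops are filtered out of the data, so
the model conditions on a non-stop outcome. An alternative would be to fold
stop mass into the no-change term; renormalization is chosen so that the
codon outcomes form a proper probability distribution, which the likelihood
and the simulator both need. The amino-acid probability is the summed mass
of the residue's sense codons; the wildtype amino acid accumulates its
synonymous-codon mass plus the no-change term.

**Selection factors.** A selection model contributes a per-site,
per-amino-acid preference ratio R (child over parent). Raw ratios can be
arbitrarily large and would push codon probabilities past 1, so they are
passed through F = 2/(1 + 1/R), which is increasing, fixes F(1) = 1, and is
bounded in (0, 2): an outcome can at most double. Each non-wildtype codon
outcome is multiplied by the F of its amino acid (synonymous outcomes have
R = 1 by construction). Remaining pathologies are handled in this order:
individual modified probabilities above 1 are clamped to 1, then if the
total non-wildtype mass exceeds 1 it is renormalized to 1 and the no-change
probability set to 0. Clamp and renormalization events are counted and
reported, never silent; with realistic rates and branch lengths they do not
occur.

Two built-in ratio sources: BLOSUM62 half-bit log-odds (R = 2^(M/2), via
biopython's matrix; the wildtype is pinned at R = 1) and deep mutational
scanning binding strengths b = −log₁₀ K_D (R = 10^(b_child − b_parent);
missing entries default to R = 1 with a warning). Note that for a symmetric
log-odds matrix the forward and reverse ratios are equal — not reciprocal:
R(X→X')·R(X'→X) = 2^M, not 1.

**Language-model scaling.** Masked-language-model adapters supply per-site
logits over the 20 standard amino acids (restricted from the model's larger
token alphabet upstream); softmax gives P(r,X). These probabilities carry no
notion of evolutionary time, so they are scaled by the Poisson mutability
1 − e^(−τ): wildtype gets e^(−τ) + (1 − e^(−τ))P, others (1 − e^(−τ))P. The
scaling recalibrates SSPs but is a positive affine map on the non-wildtype
entries, so it preserves their ranking at every τ — rank-based metrics are
unaffected; calibration-based metrics are not. The `masked-marginals` vs
`wt-marginals` tag records how logits were produced and is metadata only:
both are treated identically downstream. Model weights are never loaded;
logit tables are precomputed inputs, which keeps the tool self-contained and
lets any language model plug in behind the same file contract.

## Branch-length optimization

τ̂ maximizes the framework's log-likelihood of the child: per-nucleotide
(NT), per-codon under selection (NT-AA), or per-residue (AA). The optimizer
is deterministic bounded scalar maximization over log τ on [10⁻⁹, 10] with
tolerance 10⁻⁸ on log τ (`scipy.optimize.minimize_scalar`). The starting
point — the PCP's normalized nucleotide mutation frequency — is also kept as
a guaranteed-no-worse fallback, so the reported fit never scores below the
initializer. Under uniform rates the MLE has the closed form
τ̂ = −ln(1 − m/n)/λ, which the test suite uses as an oracle (recovered to
relative error < 10⁻⁵). Zero-probability observations contribute a floored
log (10⁻³⁰⁰) with a warning rather than −∞, keeping the search finite.

Codon sites containing `n` in parent or child are skipped entirely — in
likelihoods, distributions, and metrics — because ambiguity at one position
contaminates the whole codon's amino-acid outcome.

## Metrics

- **SSP** = 1 − P(wildtype) per site; **CSP** renormalizes the non-wildtype
  mass (sites with SSP = 0 are excluded from CSP metrics with a warning).
  For nucleotide frameworks the CSP is derived from the codon-aggregated
  amino-acid distribution.
- **Overlap** compares observed per-IMGT-position substitution counts with
  expected counts (summed SSPs): Σᵢ min(Oᵢ,Eᵢ) / Σᵢ (Oᵢ+Eᵢ)/2.
- **R-precision** per PCP with k observed substitutions: fraction of
  observed sites among the top-k SSPs. Sites tied exactly at the k-th rank
  are chosen uniformly at random; ties above the boundary are all included.
  The dataset value is the unweighted mean over PCPs.
- **Substitution accuracy**: fraction of events whose observed outcome
  attains the maximal CSP, argmax ties broken at random; every event counts
  equally regardless of PCP.
- **CSP perplexity**: exp of the mean negative log CSP of observed outcomes
  (log-space computation); zero-probability outcomes are floored at 10⁻¹⁰
  and flagged.

All tie-breaking randomness flows from one dataset-level seed recorded in
the report. Regional slices recompute each metric restricted to sites/events
in one IMGT region (defaults: FWR1 1–26, CDR1 27–38, FWR2 39–55, CDR2 56–65,
FWR3 66–104, CDR3 105–117, FWR4 118–128); insertion codes and positions
outside all ranges are "unassigned" and excluded from position-indexed
metrics but retained for PCP-level ones. Conserved-site percentile ranks use
the strictly-smaller-count fraction with a midpoint adjustment for ties.

## Data filters

Applied in order, each tallied in the filter report: (1) drop PCPs whose
parent or child translation contains a stop codon; (2) drop PCPs with
nucleotide substitution frequency above 30% (highly diverged branches are
suspect); (3) drop PCPs with no amino-acid substitution. A separate optional
pre-filter drops sequences with more than 10 mismatches to a supplied naive
reference in any window of 20 consecutive sites (dense local clusters
suggest artifacts); it is off by default because the naive sequence is
upstream information. Exclusion of naive-parent PCPs is likewise a flag, not
a default — whether such branches belong in an evaluation depends on how the
lineages were reconstructed.

## Synthetic data

The simulator draws uniform sense-codon parents and samples each child codon
from the *same* 61-outcome distribution the engines use for evaluation.
Model-consistency is the point: it makes the generating model the true model
in the exact sense the likelihood assumes, so parameter-recovery and
calibration tests are sharp. Default study conditions: 500 PCPs of length
300 nt (roughly a heavy-chain variable region), τ log-uniform on
[0.01, 0.3] (from a fraction of a mutation to tens of mutations per
sequence, bracketing the few-substitutions-per-branch regime of real
lineage data), and a 3-mer context model with log-normal(0, 0.5) rates
around a unit scale — so τ is interpretable as expected mutations per site —
and Dirichlet(1) conditional target profiles, mimicking hot/cold-spot
structure. The 3-mer width keeps the table small (64 rows) while exercising
the same context machinery as 5-mer or wider models.

What the simulator does *not* emulate: clonal family structure and shared
trees (every PCP is independent), V(D)J recombination and germline
diversity, indels, sequencing error, multi-hit mutation paths, and any
realistic per-position IMGT geometry (synthetic position maps are the
identity). Passing recovery tests therefore shows the machinery is correct
and self-consistent, not that any particular published model is good on real
repertoires.

Per-PCP RNG streams are derived as `default_rng([master_seed, index])`, so
enlarging a dataset never reshuffles earlier PCPs. When a dataset requires
at least one amino-acid substitution per PCP, children are resampled (fresh
τ each attempt, capped at 1,000 tries) and the truth record stores the
resample count: this ascertainment inflates observed counts relative to
SSPs, so calibration tests use unconditioned datasets instead.

## Known limitations

- Per-site rate models apply naive-sequence coordinates to mutated parents
  by design (that is their measurement contract), which degrades as lineages
  diverge from the naive.
- The single-hit approximation biases τ̂ slightly downward at large true τ.
- K-mer contexts crossing sequence ends are padded with `n` and fall back to
  the model's default entry; boundary sites are therefore only as good as
  that default.
- Overlap between two models is comparable only on the identical filtered
  PCP set (the pipeline guarantees this within one run).
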