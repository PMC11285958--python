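# Methods

This note documents the statistical procedures `degsig` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Input model and scope

Expression matrices are genes × samples on a log scale and are consumed
as-is: the pipeline performs no normalization, batch correction or
probe mapping, on the view that preprocessing should be explicit and
upstream.  Clinical time units are caller-declared metadata and are
never converted.  Duplicate gene ids in input files are collapsed to
the row with the highest mean (deterministic and logged).

## Mean ± SEM stratification

A per-sample score is split at x̄ ± s/√n (s with the n−1 denominator).
We read "two groups based on mean ± SEM" as: high = {x ≥ x̄ + SEM},
low = {x ≤ x̄ − SEM}, middle band excluded — two cutoffs can only yield
two groups if the intermediate band is dropped.  Boundaries are
inclusive so exact-threshold samples are kept.  Because
max(x) − x̄ ≥ s/√(n−1) ≥ SEM for any non-constant sample (and
symmetrically for the minimum), neither group can be empty in exact
arithmetic; the guard exists for degenerate floating-point inputs.
Group membership is invariant under positive affine transforms of the
score.  Whether middle-band samples should instead be assigned to a
group is an open question of the source analysis style; exclusion is
our decision and is easy to audit via the emitted assignment table.

## DEG-set construction

For each anchor gene: (1) stratify samples on the anchor's expression;
(2) keep genes with |Pearson r| > 0.2 against the anchor, computed over
*all* samples (the prefilter is described before the split, so the full
cohort is the natural universe); strictly greater, anchor excluded;
(3) run two-class unpaired SAM on the candidates and keep genes
significantly up in the anchor-high group.

The SAM statistic is d = (x̄_hi − x̄_lo)/(s + s₀) with the pooled
standard error s; with s₀ = 0 and any group sizes it equals the
classical pooled-variance t statistic.  s₀ defaults to the median of
the per-gene s values (robust and common); a Tusher-style
coefficient-of-variation minimization over s-percentile windows and a
fixed value are also available.  s₀ is computed once from the observed
labels and held fixed across permutations.

FDR estimation: high/low labels are permuted (exhaustively when the
number of arrangements fits the permutation budget, default 1000,
otherwise seeded random draws); d̄_i is the mean permuted order
statistic at rank i.  For each margin Δ taken from the observed
positive-side exceedances d − d̄, the called set is {d − d̄ ≥ Δ, d > 0};
expected false calls are the *median* over permutations of the count of
permuted statistics at or above the smallest called d; q_i is the
minimum of false/called over margins admitting gene i, with π₀ fixed at
1 (conservative, estimation deliberately omitted) and a cumulative
minimum enforcing monotonicity of q along the d ranking.  The
q-threshold defaults to 0.05 and is configurable, since no single
conventional cutoff exists for this procedure.  Only the up-regulated
side feeds the DEG sets; the symmetric down side is implemented
(`sam_select_down`, via sign negation) but off by default.

## Enrichment scoring

ssGSEA ranks the genes of one sample descending (ties broken by gene id
for reproducibility); the i-th ranked gene carries rank value G − i + 1
(top gene G).  ES = Σ_{i=1..G} [P_in^w(i) − P_out(i)] where P_in^w
weights member genes by rank^α and P_out is the ECDF of non-members.
Each partial difference lies in [−1, 1], so |ES| ≤ G, and ES depends on
the expression column only through its ranks.  α defaults to 0.75 (the
convention of the widely used single-sample implementation).  Raw ES
values are reported without cross-sample range normalization because
downstream analysis operates on per-set z-scores (n−1 sd; a constant
row maps to zeros), which supersede it.

Two-class GSEA ranks genes by signal-to-noise with class sds floored at
0.2·|class mean| (0.2 when the mean is zero); members advance a running
sum by |metric| (normalized), non-members decrement uniformly, and ES
is the maximum deviation.  NES divides ES by the mean same-sign
permuted ES; nominal p is the same-sign permuted tail fraction; FDR q
follows the standard pooled positive/negative normalized-score
procedure.  Phenotype permutation is used when both classes have ≥ 7
samples, gene-set permutation otherwise (recorded in the result).  A
set is flagged significant at FDR q < 0.25 and NES > 1.25.

## Signature classification and contrasts

Correlation profiles use one shared Pearson implementation throughout
the package, so DEG prefiltering and association profiles agree
exactly.  A signature's class is the sign of its summed r over all
profiles and predictors — the operative rule is the sign; average-
linkage hierarchical clustering on 1 − corr between signature rows is
computed only to order heatmap leaves.  Profiles are computed per
dataset and summed afterwards, which keeps per-cohort structure
inspectable.

Group contrasts (tumor/normal, primary/metastatic, pre/post,
primary/recurrent) dispatch to a two-tailed Student's t-test with
pooled variance (Student rather than Welch, matching the named test),
pairing by patient id for longitudinal contrasts when available.  Stage
trends use Spearman rank correlation with mid-rank ties — a trend
statistic chosen by us, since per-stage boxplots name none.  Raw p
values are reported without multiplicity correction, mirroring
star-threshold reporting conventions; treat them accordingly.

## Survival

Kaplan-Meier estimation and the k-group log-rank test are implemented
directly because the result objects expose the full risk-set
tabulation (at-risk, observed, expected per group) that the pipeline
reports; `lifelines` serves as an independent cross-check in the test
suite.  Ties follow the standard convention (events before censorings
at equal times).  The log-rank chi-square uses the multivariate
hypergeometric covariance over the first k−1 groups with a
pseudo-inverse guard for degenerate risk sets; for two groups it equals
the squared standardized O−E statistic, and it is invariant under any
common strictly increasing time transform.  The combined analysis
crosses two stratifications into HH/HL/LH/LL, reports the overall
3-df test and all six pairwise tests with raw p values (no
multiplicity correction — a deliberate, logged caveat).

## Synthetic cohorts

Per sample, each anchor has a standard-normal latent activity a; the
anchor's expression row is a plus observation noise (sd 0.05 by
default, small so the anchor gene is a near-faithful readout and the
empirical module-anchor correlation matches the target).  Module genes
are β·a + σε with β = ρσ/√(1−ρ²), so their correlation with a is
exactly ρ in expectation (σ = 1 by default).  Signature activities are
h = sign·γ·a₁ + ε, driven by the first anchor (γ = 0.5 by default);
member genes load on h with unit loading.  Background genes are pure
noise — an honest null for the SAM and GSEA FDRs.  Survival is
exponential with hazard λ₀·exp(θ₁a₁ + θ₂h*) for one designated
signature (λ₀ = 0.05, θ₁ = θ₂ = 0.7, chosen to give clearly separated
but overlapping survival curves at cohort sizes of a few hundred);
censoring is an independent exponential whose rate is solved
numerically so the expected censored fraction hits the target (0.2
default, typical of cohort registries).  Optional tumor/normal, stage
and paired pre/post effects add configured shifts to the anchor rows
only, leaving the co-expression and survival structure untouched.

What this does *not* emulate: count-level noise, library-size and
batch effects, heavy-tailed expression, correlated background genes,
non-proportional hazards, informative censoring, or single-cell
cluster structure.  Passing recovery tests therefore demonstrate the
correctness of the algorithms under their own assumptions, not
robustness to real-data violations of those assumptions.

## Problem sizes and reproducibility

The test suite and the acceptance script run the recovery and
calibration checks at moderate sizes chosen as the smallest cohorts at
which the effects are comfortably identifiable: DEG recovery at
n = 300 with a 100-gene module among 1000 nulls; sign recovery at
n = 500 with ten signatures; null calibrations over 10-20 seeds;
log-rank power at n = 300 and hazard ratio 2.5; four-group ordering at
n = 400.  All randomness flows from a single seed through stage-name-
salted SHA-256 derivation, so any stage can be rerun independently and
the end-to-end pipeline is byte-reproducible.

## Known limitations

* q-value estimation uses π₀ = 1; on data with many true positives the
  reported FDR is conservative.
* The gene-set permutation mode of GSEA calibrates against random sets
  of matched size, not matched co-expression; correlated sets can
  inflate significance.
* Exhaustive SAM permutation is only feasible for small groups; larger
  designs use seeded random label draws, so q values carry Monte-Carlo
  error of order 1/√B.
* The four-group survival comparison requires all four cells to be
  non-empty and reports raw pairwise p values.
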