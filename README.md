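# degsig

Anchor-gene DEG-set construction, enrichment-signature scoring and
survival stratification for bulk expression cohorts.

## The problem

In pan-cancer transcriptome studies, the activity of a regulator family
(for example the Notch ligands JAG1/JAG2, DLL1/3/4 and the receptors
NOTCH1-4) is often read out not from the regulator's own expression but
from the genes co-expressed with it.  `degsig` implements that analysis
pattern as a tested, reusable pipeline:

1. **Stratification** — samples are split on any per-sample score *x*
   into *high* = {x ≥ x̄ + SEM}, *low* = {x ≤ x̄ − SEM}, with the middle
   band excluded (SEM = s/√n, sample standard deviation with n−1).
2. **DEG sets** — for an anchor gene *A*, candidate genes are those with
   |Pearson r| > 0.2 against *A* over all samples; a two-class unpaired
   SAM (significance analysis of microarrays) then calls genes
   significantly up in the *A*-high group:
   d_i = (x̄_hi − x̄_lo) / (s_i + s₀), with permutation-based FDR q per
   gene (π₀ = 1).  Genes with d > 0 and q ≤ 0.05 form the set `A-DEG`.
3. **Enrichment** — single-sample GSEA (ssGSEA): genes are ranked per
   sample and ES = Σ_i [P_in^w(i) − P_out(i)], the integrated difference
   between the rank-weighted ECDF of set members (weight rank^α,
   α = 0.75) and the ECDF of non-members; ES rows are z-normalized
   across samples.  Two-class GSEA (signal-to-noise ranking, weighted KS
   running sum, permutation NES/p/FDR; significance at FDR q < 0.25 and
   NES > 1.25) is also provided.
4. **Signature classification** — Pearson correlations of predictors
   (anchor expression, DEG-set z-scores) against hallmark-signature
   z-scores are summed; signatures with Σr > 0 are *positive*, Σr < 0
   *negative*.
5. **Survival** — Kaplan-Meier product-limit curves and k-group
   log-rank tests for the high/low split and for the combined
   HH/HL/LH/LL four-group assignment from two stratifiers.

A synthetic-cohort generator plants co-expression modules at a target
correlation, latent signature activities with chosen signs, and
exponential survival with hazards log-linear in the latent activities,
so every stage is validated by ground-truth recovery.

## Worked example

The bundled configuration simulates a 120-sample cohort with two anchor
genes (`JAG1`, `NOTCH1`), 40-gene co-expression modules at ρ = 0.5, six
planted signatures (three positive, three negative, γ = 0.5) and
survival driven by `JAG1` activity and the angiogenesis-like signature:

```sh
degsig run-all --config examples/synthetic_config.yaml --out out
```

`out/deg/deg_sets.gmt` contains `JAG1-DEG` (109 genes) and `NOTCH1-DEG`
(55 genes).  `out/association/signature_classes.tsv` classifies the
signatures by summed correlation:

```
signature           sum_r    class
ANGIOGENESIS        1.021    positive
HYPOXIA             0.723    positive
KRAS_SIGNALING_UP  -0.121    negative
MYC_TARGETS_V1     -0.687    negative
E2F_TARGETS        -0.108    negative
G2M_CHECKPOINT     -0.629    negative
```

Five of six planted signs are recovered; `KRAS_SIGNALING_UP` (planted
positive) is flipped by chance correlations of the independent `NOTCH1`
predictors at this small n — at n = 500 with a single anchor the
classification recovers 10/10 signs (see the acceptance script below).
`out/survival/logrank.tsv` shows the survival structure: stratifying on
`JAG1` expression gives χ² = 13.7 (p = 2.1e-4), on the angiogenesis
z-score χ² = 39.0 (p = 4.3e-10), and the combined `JAG1` × angiogenesis
four-group test gives χ² = 43.5 on 3 df (p = 1.9e-9), with the
high/high group worst — matching the planted positive hazard
coefficients (θ₁ = θ₂ = 0.7).

Rerunning the same command reproduces every output byte-for-byte; all
randomness derives from the single config seed, salted per stage.

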