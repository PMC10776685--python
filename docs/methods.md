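# Methods

## Model

For one gene and one alteration class, the data are the within-cell-line
viability ranks of the gene's retained shRNAs: R_ik for shRNA i in cell line
k.  Ranks are computed per cell line over *all* retained shRNAs of all genes
(rank 1 = most depleted), so a typical value is in the hundreds and the
baseline mean is large.  The model is a negative binomial random-intercept
regression,

    R_ik | u_k ~ NB(mu_ik, theta),  mu_ik = exp(beta0 + beta X_k + u_k),
    u_k ~ N(0, sigma^2) i.i.d.,

with X_k ∈ {0,1} the line's mutant status for the gene.  The NB2 shape theta
(variance mu + mu^2/theta) absorbs the overdispersion of ranks around the
gene's mean level — including spread between shRNAs, which is deliberately
not modelled with per-shRNA effects.  The random intercept u_k absorbs
per-line shifts of the gene's whole rank profile.  Intercepts are taken
independent across cell lines (covariance sigma^2·I): there is one intercept
per line and no structure among lines is asserted; an explicit intercept
beta0 is included because ranks have a large baseline mean.

Assumptions worth stating: ranks are treated as unbounded NB counts although
they are a bounded permutation statistic; observations within a line are
conditionally independent given u_k; missing logFC entries are
missing-at-random and simply dropped.  These are pragmatic choices — the
model is a working likelihood for a rank statistic, and its validity is
demonstrated by calibration rather than by derivation.

## Likelihood and fitting

The marginal likelihood factorizes over cell lines.  Each one-dimensional
integral over u_k is evaluated by adaptive Gauss–Hermite quadrature: the
integrand's mode is found by a damped Newton iteration (the integrand is
strictly concave in u), the quadrature nodes are centred at the mode and
scaled by the curvature.  One node reproduces the Laplace approximation,
which is the default (`n_quad=1`, matching the convention of standard
mixed-model software for this family); more nodes are available and converge
to brute-force numerical integration (verified to 1e-6 against a 10^4-point
trapezoid rule in the tests).  The sigma -> 0 limit is evaluated analytically
(u ≡ 0).

Optimization is quasi-Newton (L-BFGS-B) over (beta0, beta, log theta,
log sigma) from a deterministic method-of-moments start.  A profile fit with
sigma fixed at zero is always computed as well; if it attains at least the
same likelihood, the boundary solution sigma^2 = 0 is reported.  se(beta)
comes from the inverse observed information (central finite differences) at
the optimum, over the free parameters only.  The one-sided Wald p-value is
Phi(beta_hat / se); inference is Wald, not likelihood-ratio.  Gradient
tolerance 1e-6; convergence is flagged, and non-converged fits keep their
estimates but are marked.

The Gaussian random-intercept model used by the ablation variants is fitted
by exact maximum likelihood: the fixed effects are profiled out by GLS at
each variance-component value (Woodbury identity per cluster), and the two
variance components are optimized by Nelder–Mead with the sigma_u = 0
boundary checked explicitly.  It matches statsmodels MixedLM (ML) to ~1e-5
in the tests.

## Pipeline decisions

* **Batch correction orientation.** Pool and seed stability are attributes
  of the shRNA, so the correction is fitted per cell line across shRNAs:
  y_s = alpha + delta[pool(s)] + gamma·(stab(s) − mean stab) + eps, by OLS
  with a sum-to-zero pool encoding.  Centring both terms preserves each
  line's mean; downstream ranks are invariant to that choice.  Cell lines
  with a single observed pool, or constant stability, drop the corresponding
  term with a warning.  The operation is idempotent.
* **Seeds without a stability value** are imputed with the table mean
  (zero after centring) rather than dropping the shRNA for an auxiliary
  covariate.
* **Ranking** is ascending over observed corrected values per cell line,
  ties broken by shRNA ID for determinism, missing entries skipped with the
  observed ranks kept contiguous.  Ranks are computed once, before
  concordance selection, and are not recomputed afterwards.
* **Concordant selection** keeps ceil(n/2) shRNAs per gene (never discarding
  a majority for odd n); the mean rank profile includes the shRNA being
  scored; correlations are pairwise-complete Pearson and undefined
  correlations (fewer than 3 paired observations, zero variance) score
  −inf so they are never chosen ahead of defined ones.
* **Alteration classes.** Non-missense = start/stop-codon deletions and
  insertions, frameshift and in-frame indels, nonsense, splice site;
  missense = missense mutation; amplification = GISTIC2 value 2.  Deep
  deletion (−2) is never tested but, like the other three, removes a line
  from wild-type status.  The control group is strictly wild-type; lines
  carrying only other alteration classes are excluded from both groups.
  MAF dialect strings are normalized case-insensitively with a shipped
  alias table (e.g. `Frame_Shift_Del`); unrecognized strings are tallied
  and ignored.
* **Group-size gate.** A (gene, class) is testable with ≥2 mutant and ≥2
  strictly wild-type lines contributing at least one observation; the same
  rule applies pan-cancer and per cancer type.  Cancer types need ≥4
  screened lines after preprocessing.
* **Multiple testing** is Benjamini–Hochberg within each alteration class
  (and within each cancer type for cancer-specific runs), significance at
  adjusted 0.05.  The stratification matches per-class reporting of
  discoveries.
* **Hypermutated-line filter** uses the sample standard deviation (n−1) of
  per-line mutation-record counts and a strict `>` comparison; "abundance
  below 50" is a strict `<`.  Duplicate rows are collapsed by averaging the
  observed readouts per cell line (and the abundance), since one row per
  shRNA is required downstream.

## Synthetic screens

The generator emulates the additive structure the pipeline assumes:

    logFC(s, c) = gene_effect + driver_shift·mutant + pool_offset
                + gamma·stability(seed) + cell_effect + noise

with defaults chosen as a realistic desk scale: 100 genes × 10 shRNAs × 20
cell lines; gene-effect sd 0.5, residual sd 0.8, cell-line sd 0.3 (logFC
units, the typical spread of screen readouts); pool offsets {+0.3, −0.1,
−0.2}; stability slope 0.1 on stabilities ~ N(−7, 1.5) (arbitrary energy
units); driver depletion −1.0 logFC in mutant lines; NB abundances with
mean 500 and shape 2 so a few percent of hairpins fall under the abundance
floor of 50.  Mutation and GISTIC tables are consistent with the mutant
assignments; non-driver genes receive label-only (null) mutants.  Every
replicate of the Monte-Carlo protocols draws its generator from
`default_rng([master_seed, replicate_index])`, so reports are exactly
reproducible.

What the generator does *not* emulate: realistic per-seed off-target
structure (only the scalar stability covariate), gene–gene correlation,
copy-number dosage effects on expression, or screen-quality artefacts beyond
simple missingness.  Passing tests therefore demonstrate the statistical
machinery under the model's own assumptions plus an additive batch
structure — not performance on any particular real screen.

## Simulation protocols and problem sizes

Type-I error uses random pseudo-labels (n_m ~ U{2..m} from all lines, then
n_w ~ U{2..w} from the remainder), rejection at the *raw* p < 0.05 — the
protocols report per-test error, not FDR-adjusted counts.  Replicates are
split evenly across the gene list.  The desk-scale study uses genes with at
least 8 mutant and 8 wild-type lines, mirroring the use of frequently
mutated cancer genes in this protocol; at those sizes the test is calibrated
(rejection ≈ 0.05, uniform p-values).  A known limitation: with pseudo-mutant
groups of size 2 the Wald test is anticonservative (rejection ≈ 0.10), which
is also why occasional false discoveries at tiny group sizes appear in the
end-to-end run.  Power subsamples n_m ∈ {2..10} true mutant lines and
n_w = q·n_m wild-type lines, q ∈ {1,2,3,4}.

The shipped tests and the acceptance script run reduced replicate counts
(500 null replicates, 60–200 per power setting or recovery study) — sizes
chosen so the whole suite completes in minutes on one CPU while keeping
binomial Monte-Carlo errors around one percentage point.

## Known limitations

* Wald inference with very small mutant groups (n_m = 2) is anticonservative;
  a parametric bootstrap or LRT would be better there but is out of scope.
* The NB likelihood treats ranks as unbounded counts; with very few shRNAs
  per gene the shape parameter is weakly identified and the sigma^2 estimate
  often lands on the boundary.
* Concordance selection reuses the data being tested (selection and testing
  are not sample-split); this mirrors the intended algorithm but means the
  retained set is noise-selected for small genes.
* The Gaussian-LMM ablation variants are provided for comparison, not tuned
  for robustness to heavy-tailed logFC.
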