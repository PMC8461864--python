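# Methods

## The model

labcmap matches drugs to diseases through laboratory-test signatures, the
connectivity-map idea with lab panels in place of gene expression.

**Drug effect vectors (CSCCS).** Each lab test is modelled per patient as a
linear fixed-effects panel

    y_ij = alpha_i + beta' x_ij + eps_ij,   eps_ij ~ N(0, sigma^2) iid,

where `y_ij` is patient *i*'s *j*-th measurement of the lab, `x_ij` is the
0/1 vector of drugs the patient was on at that time, and `alpha_i` is the
patient's own baseline for the lab.  Because every contrast is within
patient (a self-controlled design), time-invariant confounding is absorbed
by `alpha_i`.  The baselines are profiled out exactly: subtracting each
patient's mean response and mean exposure reduces the full least-squares
problem with one intercept per patient to ordinary regression on the
centered data.  On the centered problem we solve the lasso

    argmin_beta  1/2 ||y_c - X_c beta||^2 + lambda ||beta||_1,

reflecting the assumption that any one lab is moved by few drugs.  A
coefficient surviving a significance test (below) contributes +1 or -1 by
its sign to the drug's ternary effect vector; everything else is 0.

**Disease sign vectors.** For each lab, case and control values are
compared with the two-sided Wilcoxon rank-sum (Mann-Whitney U) test at
alpha = 0.05; significant labs get +1/-1 by comparison of the group
*means* (a deliberate convention — the direction is defined on the mean
even though the test is rank-based).  No multiple-testing correction is
applied across labs; each lab is judged at the raw threshold.

**Scoring.** Over a shared, harmonized lab catalog the repurposing
possibility score of a (drug, disease) pair is the negative dot product of
the two ternary vectors, TS = -CV_drug . CV_disease: each lab where the
drug opposes the disease adds +1 (complementary), each lab where it moves
the same way adds -1 (adverse).  TS equals (#opposed labs) - (#same-sign
labs) and is bounded by the number of labs on which both vectors are
nonzero.

**Evaluation.**  Per disease, drugs are ranked by descending score (ties
by ascending drug id).  Precision@K is the fraction of the top K that are
known indications.  For fold enrichment the ranked list is cut into
consecutive bins of `group_size` (last bin keeps the remainder) and each
bin's gold density is divided by overall density, FE = (n/m)/(N/M); the
least-squares slope of FE against bin order summarizes the trend (negative
is good).  Gold drugs absent from the ranked universe are dropped from N
with a logged count.

## Numerical and inferential choices

* **Lambda selection.**  Patient-grouped k-fold cross-validation (default
  k = 5): patients, not rows, are partitioned, respecting the
  self-controlled structure.  The default applies the one-standard-error
  rule — the largest lambda whose CV error is within one SE of the minimum.
  Plain CV minimization over-selects under the null (in our null
  simulations only ~70% of pure-noise replicates kept an empty support;
  with the 1-SE rule, 100%), while power for unit effects at realistic
  sample sizes is unaffected.  `one_se=False` restores plain CV-min, and a
  fixed numeric lambda can be configured instead.
* **Coefficient p-values.**  Post-selection refit: unpenalized least
  squares on the lasso support over centered data, classical two-sided
  t-tests with residual degrees of freedom n − N − s (N absorbed patient
  intercepts, s the support size).  Off-support drugs get p = 1; if the
  support exhausts the degrees of freedom all p-values are 1 with a
  warning.  Post-selection t-tests are mildly anti-conservative; the
  debiased lasso would be the principled alternative and is out of scope.
* **lambda = 0** uses the minimum-norm least-squares solution (exact under
  rank deficiency); lambda > 0 delegates to coordinate descent with the
  objective rescaled so the penalty is on the unnormalized sum of squares.
* **Rank-sum test.**  Exact null distribution when both groups have at
  most 20 observations and no ties (equivalent to a Mann-Whitney table
  look-up); otherwise the normal approximation with tie and continuity
  correction.  Missing lab values are dropped pairwise per lab.
* **Ties.**  A significant rank-sum test with exactly equal group means is
  called 0 (logged).  Score ties in rankings break by ascending drug id so
  evaluation is reproducible.
* **Thresholds.**  Drugs with fewer than `min_patients_per_drug` distinct
  exposed patients (default 1000, mirroring the production setting) are
  excluded before fitting; diseases need `min_samples_per_disease` case
  samples.  Desk-scale configs lower both.
* **Bi-clustering.**  Spectral co-clustering with a fixed seed.
  Co-clustering assigns rows and columns to one shared set of clusters, so
  the row and column cluster counts must be equal; scores are shifted to
  be positive beforehand, as the spectral method requires nonnegative
  data.  A constant matrix returns identity orders with a warning.

## The synthetic world

The generator draws data *exactly* from the model above, which is what
makes the oracle tests sharp: with sigma = 0 any fixed-effects fit must
reproduce the planted beta to machine precision.

* **Longitudinal arm.**  Per-patient panel lengths J_i uniform on a
  configured range (default 5–10, exercising unbalanced panels); baselines
  alpha_i ~ N(50, 10^2) per patient per lab; exposures i.i.d.
  Bernoulli(0.15) per drug per measurement time, shared across the labs
  measured at that time; noise sd 1.  Planted effects have |beta| = 1 — a
  one-noise-sd shift, the scale of a clinically visible lab change.
* **Survey arm.**  Cases ~ N(mean + shift, sd), controls ~ N(mean, sd) per
  lab, default 400 per group with shifts of 0.8 sd on four labs per
  disease — large enough for near-certain detection at those sample sizes.
* **The pipeline's planted truth** is structured rather than uniformly
  random: drug m acts on a contiguous footprint of three labs starting at
  lab m (mod L), even-numbered drugs lowering and odd-numbered drugs
  raising them; disease k elevates four contiguous labs starting at lab k.
  Lowering drugs overlapping a disease's footprint are net complementary
  (therapeutic in this world), raising drugs are adverse, so true scores
  span −3..+3 and the truth-built gold standard (drugs with strictly
  positive true score) is well separated from the rest.  Uniform random
  sparse effects remain available (`TrueDrugEffects.random_sparse`) and
  drive the sign-recovery benchmarks.
* **What the world omits.**  No prescription intervals, dosing,
  drug–drug interactions, exposure autocorrelation, survey weighting, or
  informative missingness.  A green end-to-end test therefore establishes
  the estimator and plumbing are correct under the stated model — not that
  the method is robust to real-EHR confounding.

## Known limitations

* Post-selection inference is approximate (see above).
* Direction by mean comparison can disagree with the rank-based test
  under heavy skew; the convention is kept for fidelity to the framework.
* The score weights all labs equally even though a few (cholesterol, LDL,
  HDL, triglycerides) dominate real signatures.
* Exposures are treated as exogenous; confounding by indication is outside
  the model.
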