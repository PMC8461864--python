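# labcmap

Clinical connectivity mapping for drug repurposing from laboratory-test
signatures.

A drug that pushes lab results in the direction *opposite* to a disease's
characteristic derangement is a repurposing candidate.  labcmap builds that
inference chain from two routine data sources:

1. **Drug effect vectors** from longitudinal EHR-style data.  Each lab is
   modelled as `y_ij = alpha_i + beta' x_ij + eps_ij` with a per-patient
   baseline `alpha_i` (a continuous self-controlled case series).  The
   baselines are profiled out by within-patient centering and the drug
   effects `beta` are estimated with an L1 penalty,
   `argmin 1/2 ||y_c - X_c b||^2 + lambda ||b||_1`, lambda chosen by
   patient-grouped cross-validation.  Significant coefficients
   (post-selection t-tests, p < 0.05) become +1/-1 entries of a ternary
   drug -> lab vector.
2. **Disease sign vectors** from case/control survey data: a two-sided
   Wilcoxon rank-sum test per lab at p < 0.05, direction by comparison of
   group means.
3. **Scoring**: over a harmonized lab catalog, each drug-disease pair gets
   `TS = -CV_drug . CV_disease` — +1 per complementary lab, -1 per adverse
   lab, so positive scores mean net therapeutic potential.

Rankings are evaluated against a gold standard of known indications by
precision@K and the fold-enrichment test `FE = (n/m)/(N/M)` over
consecutive rank bins, and the score matrix can be bi-clustered to expose
related drug/disease blocks.  A seeded synthetic-data generator with
planted effect directions makes the whole pipeline testable offline.

## Worked example

Score a glucose/lipid-panel disease signature against two drug signatures:

```python
import pandas as pd
from labcmap import SignVector, repurposing_score

labs = ["alp", "chol", "glu", "hdl", "ldl", "tg"]
t2d = SignVector("t2d", pd.Series(dict(zip(labs, [-1., 1, 1, -1, 1, 1]))))
statin_like = SignVector("statin_like", pd.Series(dict(zip(labs, [0., -1, 0, 0, -1, 0]))))
adverse = SignVector("adverse", pd.Series(dict(zip(labs, [0., 1, 1, 0, 0, 0]))))

print(repurposing_score(statin_like, t2d))  # 2.0
print(repurposing_score(adverse, t2d))      # -2.0
```

The first drug lowers cholesterol and LDL while the disease raises both:
two complementary labs, score +2.  The second raises them alongside the
disease: two adverse labs, score -2.

Run the full pipeline on a simulated world:

```sh
labcmap run --config examples/config_small.yaml
```

which writes `ehr.tsv`, `survey_*.tsv`, `gold_standard.csv`,
`drug_vectors.csv`, `disease_vectors.csv`, `score_matrix.csv`, per-disease
rankings, `evaluation.csv`, `fold_enrichment.csv`, `clustered_scores.csv`
and a run manifest under `outputs/small/`, printing per-disease summaries
such as

```
disease_id  precision_at_5  precision_at_10  fe_slope
disease_00             1.0              0.8 -0.900000
disease_01             1.0              0.8 -0.900000
disease_02             1.0              0.8 -0.900000
disease_03             1.0              0.7 -0.971429
```

precision@5 = 1.0 means every top-5 ranked drug for the disease is a true
indication in the planted gold standard; the negative `fe_slope` means
known indications concentrate in the top rank bins.  Stages can also be
run individually (`simulate`, `drug-vectors`, `disease-vectors`, `score`,
`evaluate`, `cluster`) with identical outputs.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic world from the given seed, runs every stage of
the pipeline end to end (drug-effect estimation, disease sign tests,
scoring, ranking, evaluation) and writes the results JSON.

See `docs/methods.md` for the model, the tuning and inference choices, and
what the synthetic world does and does not establish.
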