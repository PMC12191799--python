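# ratiosurv

Anchor-gene expression-ratio survival screening for bulk RNA-Seq cohorts.

Some genes matter for patient outcome not through their own expression
level but through their balance with a specific partner gene. `ratiosurv`
screens every feature `g` of an expression matrix for such relationships
with a chosen **anchor gene** `A` (the motivating application is the
ovarian tumor suppressor OPCML in stage-IIIC serous ovarian cancer): for
each gene it forms the per-subject ratio

    r_g(s) = log2(x_A(s) + 4) / log2(x_g(s) + 4),

bifurcates the cohort at the median ratio, and contrasts the two halves
with Kaplan–Meier/log-rank tests and a univariate Cox model. The hazard
ratio (high-ratio vs low-ratio group) is symmetrized,

    HRsym = HR − 1 if HR ≥ 1, else −(1/HR) + 1,

and Z-scored across the screen into **HRz**, so both tails live on one
scale. Significance requires (i) the ratio split to be at least 10% more
significant than a median split on the gene's own expression (the
*improvement filter*), and (ii) |HRz| beyond two-tailed boundaries that are
calibrated empirically by Monte Carlo: the whole screen is re-run on
permuted expression and survival data and the null HRz quantiles at
0.025/0.975 become the thresholds (they land very near ±2). Hits in the
two tails (`OPCML_plus` / `GENEi_plus`) feed hypergeometric
over-representation analysis against GMT gene-set collections, duplicate
functions collapse to their most conservative p-value, functions are
clustered by member-gene Jaccard distance, and a literature-relevance
score (geometric mean of per-gene citation counts, "OVca") produces a
ranked triage table.

A fully-featured synthetic-cohort generator (expression, ratio-linked
survival, planted gene sets, citation tables) makes every stage testable
without any external download. See `docs/methods.md` for the model,
defaults, and limitations.

## Worked example

Plant one gene whose anchor ratio doubles the hazard of its high-ratio
group in a 189-subject synthetic cohort, then screen for it:

```python
import numpy as np
import ratiosurv as rs

sim = rs.SimulationConfig(
    n_subjects=189, n_features=500, seed=7,
    effect_feature_ids=("G00010",), true_log_hazard=float(np.log(2)),
)
expr = rs.generate_expression(sim)
cohort = rs.generate_survival(sim, expr)

screen = rs.RatioSurvivalScreen(anchor="OPCML").fit(rs.log2p4_transform(expr), cohort)
cal = rs.calibrate(rs.log2p4_transform(expr), cohort, "OPCML",
                   n_iterations=10, rng_seed=7)
records = rs.classify_groups(screen.records_, cal.thresholds("empirical"))
```

This prints (via the summary statements in the example script):

```
null FP rate at |HRz|>2: 0.0441
empirical HRz thresholds: [-1.902, 1.991]
planted gene G00010: HR=1.693  p_ratio=4.41e-04  p_single=0.667  HRz=+2.32  group=GENEi_plus
features classified: 18 of 499
```

Reading the numbers: on permuted (null) data ~4–5% of features exceed the
±2 boundaries, and the empirical thresholds sit close to ±2, as expected
for a centered unit-variance statistic. The planted gene's ratio split is
highly significant (p ≈ 4×10⁻⁴) while its own expression split is not
(p ≈ 0.67) — exactly the synergy pattern the screen targets — so it passes
the improvement filter and lands in the `GENEi_plus` tail. The ~18 total
classified features include null false positives at roughly the calibrated
rate.

## Command line

Every stage is also a `ratiosurv` subcommand operating on plain TSV/GMT
files, and a whole run is reproducible from one YAML config:

```bash
ratiosurv simulate --out-dir demo --seed 7
ratiosurv preprocess --expr demo/expression.tsv --clinical demo/clinical.tsv \
    --anchor OPCML --stage IIIC --out-dir demo/pre
ratiosurv screen --expr demo/pre/expression_log2p4.tsv \
    --clinical demo/pre/clinical_filtered.tsv --out demo/screen.tsv
ratiosurv calibrate --expr demo/pre/expression_log2p4.tsv \
    --clinical demo/pre/clinical_filtered.tsv --iterations 25 --seed 7 \
    --out demo/calibration.json
ratiosurv run --config run.yaml        # simulate → … → triage, with manifest
```

Runs write a `manifest.json` with the config hash, seed and SHA-256 of
every output; identical config + seed reproduces every file byte for byte.

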