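# prfcohort

A simulation-and-analysis pipeline for studying how the anatomy of human
early visual cortex (V1/V2) relates to the position tuning of its neural
populations and to perceptual acuity.

The scientific setting: across people, visual cortical **surface area**
varies about 1.5–2-fold while **cortical thickness** varies from ~1 to
~4 mm across locations within a person. Population receptive field (pRF)
mapping measures, for every cortical location, the width σ of the 2D
Gaussian that best describes the visual-field region driving its BOLD
response ("position tuning width"); adaptive psychophysics measures the
smallest position difference an observer can discriminate at matched
visual-field positions. The question is how σ and the discrimination
threshold co-vary with thickness (locally) and surface area (globally).

Because no such dataset is publicly deposited, the package is built
around a **synthetic cohort generator** whose planted ground truth makes
every analysis stage verifiable by parameter recovery: thicker cortex →
wider tuning and higher thresholds; larger surface area → narrower tuning
and lower thresholds, with the eccentricity dependence (slope and
intercept of σ(e) and threshold(e)) tied to surface area. User-supplied
real data in the documented per-vertex TSV schema can be analyzed through
the same functions.

## What is in the box

| module | contents |
| --- | --- |
| `synthetic_cohort` | seeded cohorts: vertex tables (eccentricity, polar angle, thickness, folding class, vertex area), ground-truth tuning width σ = σ₀ + σ₁·e + β_t·(t − t̄) + β_S·(S − S̄) + ε, and psychometric observers at the 13 standard positions |
| `prf` | bar stimulus (64 apertures = 8 directions × 8 steps), double-gamma HRF, BOLD forward model y = b + a·(drive ⊛ h), and a two-stage 2D-Gaussian fitter (coarse grid with closed-form gain, Nelder–Mead refinement) |
| `anatomy` | exponential eccentricity-distribution fit y = a·e^(−bx) with coverage fraction e^(−b·0.25) − e^(−b·7.2), histogram Gaussian thickness fit, surface-area accounting, sulcus/gyrus × parafovea/perifovea paired-t contrasts |
| `psychophysics` | Weibull 2AFC observers, transformed 2-down-1-up staircases converging on the 70.7%-correct point, 13-position threshold maps, log-polar nearest-position projection onto the cortical vertex table |
| `stats` | permutation Spearman correlation (exhaustive for n ≤ 8), single-step max-statistic FWE correction, group-mean centering for intra-/inter-individual decomposition, eccentricity × participant/thickness data grids, fixed-eccentricity and eccentricity-resolved analyses |
| `pipeline` / `cli` | configured, seeded end-to-end runs with TSV/JSON outputs and provenance |

## Worked example

```python
import numpy as np
from prfcohort import (CohortConfig, generate_cohort, measure_thresholds,
                       fixed_eccentricity_analysis)

cohort = generate_cohort(CohortConfig(areas=("V1",), seed=5))
maps = {
    pid: measure_thresholds(cohort.observers[pid],
                            rng=np.random.default_rng(i), participant_id=pid)
    for i, pid in enumerate(cohort.participant_ids())
}
areas = {a.participant_id: a.surface_area["V1"] for a in cohort.anatomy}
res = fixed_eccentricity_analysis(cohort.vertices, maps, areas,
                                  n_perm=999, rng=1)
for r in res.results:
    print(f"{r.pair:28s} rho={r.rho:+.3f} p_fwe={r.p_fwe:.4f} (n={r.n})")
```

prints (seed 5; 20 participants × 6 positions at 4.7° eccentricity):

```
width~threshold              rho=+0.820 p_fwe=0.0010 (n=120)
width~threshold_intra        rho=+0.386 p_fwe=0.0010 (n=120)
width~threshold_inter        rho=+0.827 p_fwe=0.0010 (n=120)
width~thickness              rho=+0.398 p_fwe=0.0010 (n=120)
width~thickness_intra        rho=+0.849 p_fwe=0.0010 (n=120)
width~thickness_inter        rho=+0.384 p_fwe=0.0010 (n=120)
width~area                   rho=-0.858 p_fwe=0.0010 (n=120)
threshold~thickness          rho=+0.367 p_fwe=0.0010 (n=120)
threshold~thickness_intra    rho=+0.469 p_fwe=0.0010 (n=120)
threshold~thickness_inter    rho=+0.375 p_fwe=0.0010 (n=120)
threshold~area               rho=-0.735 p_fwe=0.0010 (n=120)
```

Reading: tuning width correlates positively with the discrimination
threshold (wider tuning, poorer acuity) and with local thickness, and
negatively with surface area; the `intra`/`inter` rows repeat each
correlation after subtracting participant means (within-subject
component) or position means (between-subject component). `p_fwe` is the
max-statistic permutation p-value corrected over each family. All signs
match the planted generative model. (Exact rho values reflect one run of
the staircases; the numbers above are what this seed prints.)

The same run from a shell:

```sh
prfcohort run-all --config config.yaml --seed 5 --out results/
```

writes `vertices.tsv`, `thresholds.tsv`, the correlation tables, and
`report.json` with config-hash provenance.

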