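# radgen

Whole-volume MRI radiomic phenotyping and radiogenomic signature analysis
for endometrial cancer cohorts.

`radgen` implements an end-to-end discovery/validation pipeline:

1. **Radiomic profiling** — 53 whole-volume features per case: 17 per MRI
   channel (VIBE+C, ADC, b1000: first-order statistics, in-mask GLCM and
   GLRLM texture, Gabor energies, intensity-cluster descriptors) plus tumor
   volume and the normalized surface/volume ratio.
2. **Normalization** — per-field-strength (1.5T/3T) Z-transform; training
   parameters are frozen and reapplied to validation cohorts.
3. **2+1 clustering** — k-means split into two clusters, then re-split of the
   aggressive cluster, yielding phenotypes 1, 2a and 2b; nearest-centroid
   assignment for new cases, feature-importance ranking, and a
   mask-perturbation (dilate/erode) robustness protocol. A deterministic PAM
   k-medoids variant is included for comparison.
4. **Differential expression** — in-package SAM (significance analysis of
   microarrays) with the moderated d-statistic, permutation null, and
   median-based FDR, in two-class and multiclass form.
5. **Gene signature** — overlap of the two SAM runs; per-sample score =
   sum of z-normalized expression over up-genes minus down-genes,
   dichotomized at the cohort mean.
6. **Cohort statistics** — chi-square/Fisher tables with printed-style
   rounding, Kaplan–Meier/log-rank survival analysis, robust regression.
7. **Synthetic cohorts** — 3D tumor phantoms (irregular surfaces, per-group
   textures, scanner batch offsets, partial-volume edges), planted expression
   signatures and survival, for validation and simulation studies.

## Quick start

```python
from radgen import RunConfig, run_discovery
from radgen.synthetic import generate_cohort

cohort = generate_cohort(n_cases=150, seed=0)
survival = cohort.manifest.set_index("case_id")[["time_months", "event"]]
result = run_discovery(cohort.cases, survival=survival,
                       expression=cohort.expression, config=RunConfig(seed=0))
print(result.summary())
```

Command line:

```bash
radgen simulate --n-cases 150 --seed 0 --out cohort/
radgen run-discovery --manifest cohort/manifest.csv --expression cohort/expression.tsv --out run/
radgen run-validation --manifest newcohort/manifest.csv --model run/ --out val/
```

Run `radgen --help` for the full list of subcommands (`extract-features`,
`normalize`, `fit-clusters`, `assign`, `importance`, `perturb`, `sam`,
`build-signature`, `score`, `survival`, `crosstab`, ...).

## Testing

```bash
python -m pytest -q tests/            # unit + acceptance suites
python scripts/acceptance.py --seed 1 --out acceptance.json
```

The acceptance suite (`tests/test_acceptance.py`) contains one test per
acceptance criterion. One assertion — exact signature recovery in ≥90% of
replicates under the pinned "median FDR + smallest delta" SAM rule — fails
by design of the selection rule itself, not by implementation error; see
`docs/methods.md` ("Known limitation") for the analysis. All planted genes
are recovered in every replicate; the failures are 1–2 extra null genes.

## Layout

- `src/radgen/image.py` — NIfTI I/O, masks, morphology
- `src/radgen/features.py` — radiomic features and the Z-transform
- `src/radgen/cluster.py` — 2+1 clustering, assignment, perturbation protocol
- `src/radgen/signature.py` — SAM, signature construction and scoring
- `src/radgen/stats.py` — cohort statistics and survival analysis
- `src/radgen/synthetic.py` — phantom cohorts and planted truth
- `src/radgen/pipeline.py`, `src/radgen/cli.py` — orchestration and CLI
- `docs/methods.md` — method definitions and validation design
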