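# seromir

Tumor-agnostic blood tests for bone and soft-tissue sarcoma are built from
circulating microRNA profiles: serum is hybridized to a miRNA expression
array, each array is background-corrected against its negative-control
probes and rescaled by three internal-control miRNAs, candidate markers
are funnelled through abundance, cross-validation, cluster-trend and
differential screens, and the surviving markers are combined into a linear
diagnostic *index* by Fisher's linear discriminant analysis.  `seromir`
implements that entire analysis chain as a tested Python library and CLI,
together with a synthetic serum-miRNA study generator so every stage can be
exercised, calibrated and benchmarked without access to patient data.

It is aimed at biostatisticians and bioinformaticians who want to study,
stress-test or re-apply this class of serum-miRNA classifier pipeline.

## The model

For log2 marker levels `x` and classes benign (0) / malignant (1), the
index is the two-class Fisher discriminant with an equal-prior midpoint
intercept:

```
w = S_pooled^-1 (mu_1 - mu_0)
score(x) = w'x - w'(mu_0 + mu_1)/2
```

A score **≥ 0 calls sarcoma** (the boundary is inclusive).  Marker panels
of sizes 2–9 are searched exhaustively; each subset is scored by
leave-one-out cross-validation (refit on n−1 samples, classify the
held-out sample) and the panel with the highest LOOCV accuracy wins, ties
going to higher LOOCV AUC and then to the smaller panel.  The library also
ships the eight published index formulas (Index I–VIII) as a built-in
catalog, e.g. Index VI:

```
0.87·miR-4736 + 0.52·miR-6836-3p − 1.14·miR-4281 + 1.31·miR-762
+ 0.59·miR-658 − 0.22·miR-4649-5p − 0.15·miR-4665-3p − 15.9
```

Upstream, each array passes QC when the negative-control coefficient of
variation is < 0.15 and fewer than 10 probes are flagged; a probe is
*present* when its signal exceeds the 5%-trimmed negative-control
mean + 2 SD; present probes are background-subtracted and log2-scaled,
absent ones floored 0.1 log2 units below the array minimum; and all values
are shifted so the linear mean of miR-149-3p, miR-2861 and miR-4463 equals
a preset level.  Marker selection keeps probes abundant in > 50% of
malignant or benign samples (log2 > 6), with univariate LOOCV score > 0.6,
sitting in an average-linkage cluster whose mean rises strictly
healthy < benign < malignant, and differentially expressed (pooled t-test
p < 0.05, malignant higher) on a relative-expression (2^−ΔCt-scale)
matrix.

## Worked example

```python
from seromir import CohortSpec, PlantedMarker, PipelineConfig, run_pipeline

spec = CohortSpec(
    n_healthy=150, n_benign=150, n_malignant=150, n_mirna=300, seed=42,
    planted_markers=(
        PlantedMarker("miR-4736", 0.5, 2.0),
        PlantedMarker("miR-6836-3p", 0.5, 2.0),
        PlantedMarker("miR-762", 0.5, 2.0),
    ),
)
result = run_pipeline(PipelineConfig(cohort_spec=spec))
```

This simulates a 450-sample study (150 each of healthy, benign, malignant,
split evenly across discovery/training/validation cohorts) in which three
markers rise by +0.5 log2 in benign and +2.0 log2 in malignant serum, then
runs the full pipeline.  It prints, via the fields of `result`:

```
funnel: 293 abundant -> 17 LOOCV -> 13 step-wise -> 3 differential
best index markers: ['miR-4736', 'miR-6836-3p', 'miR-762']
coefficients: [2.307, 1.679, 2.263]
intercept: -68.795
validation: sensitivity 0.840 (95% CI 0.715-0.917), specificity 0.990,
            accuracy 0.940, AUC 0.985
```

The funnel narrows 300 target probes to exactly the three planted markers,
the search refits a three-marker index on the training cohort, and the
held-out validation cohort estimates its diagnostic performance (Wilson
intervals for proportions, DeLong for the AUC).

The same flow is available from the shell:

```
seromir simulate --config cohort.yaml --out study/
seromir preprocess --scans study/scans --meta study/metadata.tsv --out matrix.tsv
seromir select   --matrix matrix.tsv --meta study/metadata.tsv --out selection.json
seromir search   --matrix matrix.tsv --meta study/metadata.tsv \
                 --candidates panel.txt --sizes 2:9 --out search.json
seromir evaluate --matrix matrix.tsv --meta study/metadata.tsv --index VI --out report.json
seromir run      --config pipeline.yaml --out run/ --seed 7
```

A reader for GEO series-matrix text files (`seromir.geo.read_series_matrix`)
loads externally deposited, already-normalized cohort matrices, so the
published Index VI can be applied to real data with
`seromir evaluate --index VI` when such a file is available locally.

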