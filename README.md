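# methdrift

Paired longitudinal analysis of colonic DNA methylation drift in aspirin
users vs nonusers, as a tested Python pipeline:

- **core_io** — validated domain types (beta matrix, sample sheet, probe
  annotation, run config) with TSV readers/writers (`NA` for missing,
  1-based coordinates).
- **cohort** — synthetic paired-cohort generator (31 subjects × 2 colon
  locations × 2 timepoints by default) with planted aspirin-dependent
  gain/loss CpGs, age-linear clock CpGs, chip batch structure, and a
  ground-truth registry for recovery scoring.
- **preprocess** — beta/M transforms (with the 1e-07 clamp), detection-p and
  mask-list probe filtering, most-variable-CpG selection, PCA.
- **diffmeth** — per-location paired multivariable regression on M values
  (subject blocking; BMI/polyps/batch covariates; exactly-aliased age column
  dropped and reported), empirical-Bayes variance moderation
  (digamma/trigamma moment matching), BH adjustment, U/Nu dmCpG catalog
  with hyper/hypo direction, percent methylation change, and the
  per-sample methylation index (MI).
- **clocks** — generic epigenetic-clock engine: coefficient-table
  evaluation with the log-linear age transform, k-NN imputation of missing
  clock CpGs, age-acceleration residuals (AAR), clock-CpG change summaries.
- **enrichment** — two-sided Fisher region/CGI enrichment, one-sided
  pathway over-representation with CpGs collapsed to unique genes,
  TSG/oncogene/epigenetic-regulator overlap reports.
- **pipeline / cli** — end-to-end orchestration producing per-stage TSVs
  and a deterministic JSON run report, plus exact small-sample
  signed-rank / rank-sum / Shapiro–Wilk group tests.

## CLI

```sh
# generate a synthetic cohort (beta, samples, annotation, clock, truth TSVs)
methdrift simulate --seed 7 --outdir cohort/

# run the analysis from a YAML config (flat keys mirroring AnalysisConfig)
methdrift run --config config.yaml

# pretty-print a finished run's report.json
methdrift report --outdir out/
```

A minimal `config.yaml`:

```yaml
beta_path: cohort/beta.tsv
sample_sheet_path: cohort/samples.tsv
annotation_path: cohort/annotation.tsv
clock_paths: [cohort/clock.tsv]
output_dir: out
seed: 7
```

Real published clock coefficient tables are not bundled; any clock can be
supplied via the documented TSV schema (`# name:` / `# intercept:` /
`# transform:` / `# adult_age:` header lines followed by
`probe_id<TAB>weight` rows).

## Acceptance

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence, moderated-t identities, hyperparameter recovery, FDR/power
control, direction/set logic, MI and clock recovery, pipeline
determinism), one test per criterion. The report script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the pipeline end-to-end on a seeded synthetic cohort and writes the
acceptance-target JSON (empty: no numeric paper targets are reproducible
offline at desk scale, so acceptance is property- and recovery-based).
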