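# cqpanel

Two-stage qPCR miRNA panel analysis on quantitation-cycle (Cq) matrices:

* **I/O & detection rule** — delimited Cq matrices (miRNA rows, sample
  columns) with blank/sentinel cells and Cq ≥ 40 (configurable) treated
  as undetected, never imputed; sample sheets with group / sample-set /
  clinical metadata; canonicalized miRNA lists; cohort summaries; the
  both-groups detection filter.
* **Normalization** — global-mean ΔCq (dense discovery panels) and
  multi-reference ΔCq (targeted validation panels), with reference
  probes selected by a geNorm-style pairwise-variation stability ranking
  (M values, iterative exclusion).
* **Differential statistics** — per-miRNA two-group t tests (Welch or
  Student) on ΔCq, Benjamini–Hochberg FDR q values, ΔΔCq / −ΔΔCq effect
  sizes and strict-threshold candidate selection (q < 0.05,
  |ΔΔCq| > 1.0 by default).
* **Concordance** — cross-cohort direction agreement with Spearman rank
  correlation, Venn-partition list overlaps, matched-pair comparisons.
* **Simulation** — a seeded generator of Cq panels with per-miRNA
  baselines, per-sample loading offsets, additive group effects on a
  spiked subset, designed low-noise reference probes, Gaussian noise and
  right-censoring at the detection limit, plus recovery scoring.
* **Pipeline** — an orchestrated discovery → validation → concordance
  run with PCA, hierarchical clustering, volcano data, provenance
  logging and deterministic CSV outputs.

## CLI

```sh
cqpanel simulate --seed 7 --out sim/                 # cq.csv, samples.csv, truth.json
cqpanel summarize sim/samples.csv
cqpanel normalize sim/cq.csv --method global_mean --out dcq.csv
cqpanel select-refs sim/cq.csv --k 5 --out refs.txt
cqpanel normalize sim/cq.csv --method multi_reference --refs refs.txt --out dcq_ref.csv
cqpanel diff sim/cq.csv sim/samples.csv --q-max 0.05 --ddcq-min 1.0 --out diff.csv
cqpanel concord --set1 diff_a.csv --set2 diff_b.csv --panel panel.txt --out conc.csv
cqpanel overlap up_a.txt up_b.txt --out overlap.csv
cqpanel report diff.csv --out report/
cqpanel run --config pipeline.yaml
```

A minimal `pipeline.yaml` running everything on simulated data:

```yaml
outdir: out
seed: 7
simulate:
  n_mirna: 300
  n_up: 20
  n_down: 20
  effect_cycles: 2.0
```

For real data, replace `simulate:` with `discovery_cq`,
`validation_cq` and `sample_sheet` paths (optionally `panel` and
`references` list files).

## Library sketch

```python
import cqpanel as cq

table = cq.read_cq_table("cq.csv")            # 40-cycle discard rule applied
sheet = cq.read_sample_sheet("samples.csv")
filt  = cq.filter_detected(table, sheet)       # detected in >=1 sample of each group
norm  = cq.global_mean_normalize(filt.table)
diff  = cq.differential_table(norm, sheet, t_variant="welch")
up, down = cq.select_candidates(diff, q_max=0.05, ddcq_min=1.0)
```

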