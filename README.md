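# stressmodes

Plants in the field rarely face one stress at a time, and a plant's
transcriptome under *combined* stresses is not the sum of its responses to
each stress alone. `stressmodes` analyses a four-condition RNA-seq
experiment — unstressed control (CK), cold (CT), drought (DT) and combined
cold + drought (CD) — and asks how predictable the combined-stress response
is from the single-stress ones: which genes respond the same way everywhere,
which single-stress responses are canceled or carried over under the
combination, which behaviours emerge only when the stresses co-occur, and
which genes are the best candidates for engineering combined-stress
resistance.

## What it computes

Starting from a gene-level count matrix and a sample design table, the
package

1. **Differential expression** — a minimal negative-binomial engine:
   median-of-ratios size factors *s<sub>j</sub>*, a pooled method-of-moments
   dispersion per gene under var = μ + φμ², a Wald test of
   *L* = log₂((m̄ₜ + c)/(m̄₀ + c)) for each treatment versus CK, and
   Benjamini–Hochberg adjustment. A DEG is a gene with adjusted *p* < α
   (default 0.05).
2. **Transcriptional response modes** — each gene's significance-gated sign
   pattern (s<sub>CT</sub>, s<sub>DT</sub>, s<sub>CD</sub>) ∈ {−1,0,+1}³ is
   matched to one of 26 predefined expression profiles, which aggregate into
   five interaction modes: **similar**, **independent**, **combinatorial**,
   **canceled** and **prioritized**. The prioritized + combinatorial +
   canceled share is the *unpredictable* fraction of the transcriptome —
   behaviour that single-stress experiments cannot anticipate. Mode
   fractions are checked for stability across top-N significant gene sets.
3. **Set algebra** — the three-way Venn decomposition of DEG sets (overall
   and split by direction), derived overlap percentages, and the cumulative
   |log₂FC in CD| of the top-N most significant CT- and DT-responders (each
   single stress's contribution to the combined response).
4. **Candidate selection** — genes up-regulated in all three treatments
   whose CD fold change exceeds both single-stress fold changes, subgrouped
   by hierarchical clustering and joined with annotation / senescence-effect
   tables.
5. **Synthetic data** — a negative-binomial simulator that plants known
   modes and fold changes per gene, so the whole pipeline is testable with
   ground truth.

Bench-validation helpers (`stressmodes.metrics`) cover the Fv/Fm =
(Fm − Fo)/Fm quantum yield and the 2^−ΔΔCt qPCR fold change.

## Worked example

```python
from stressmodes import SimConfig, StressResponseModel, simulate_dataset

cfg = SimConfig(n_genes=2000, rng_seed=7)   # |L|=2, phi=0.1, 3 replicates
truth, design, counts = simulate_dataset(cfg)

model = StressResponseModel(counts, design)
res = model.fit(alpha=0.05)
print(res.summary())
```

```
                 Combined-Stress Response Model
================================================================
No. genes:                        2000
No. samples:                        12
  replicates CK:                     3
  replicates CT:                     3
  replicates DT:                     3
  replicates CD:                     3
Significance (adj. p):            0.05
Median dispersion:              0.0803
----------------------------------------------------------------
contrast        DEGs      up    down    median |L|
CT vs CK        1442     705     737         1.948
DT vs CK        1394     700     694         1.955
CD vs CK        1480     734     746         1.967
================================================================
```

The fitted dispersion (median 0.08) and effect sizes (median |log₂FC| ≈ 2)
recover the simulation's parameters (φ = 0.1, |L| = 2). Downstream analyses
hang off the results object:

```python
summary = res.mode_summary(top_n=500)   # union of top-500 DEGs per contrast
for mode, frac in summary.fractions.items():
    print(f"{mode:>14}: {summary.counts[mode]:4d}  ({100 * frac:.1f}%)")
print(f"{'unpredictable':>14}: {summary.unpredictable_count:4d}"
      f"  ({100 * summary.unpredictable_fraction:.1f}%)")
```

```
       similar:  280  (31.8%)
   independent:  263  (29.9%)
 combinatorial:   88  (10.0%)
      canceled:  215  (24.4%)
   prioritized:   34  (3.9%)
 unpredictable:  337  (38.3%)
```

About 38% of the assigned genes fall in modes whose CD behaviour is not
predictable from CT or DT alone. Candidate selection:

```python
cands = res.candidates(margin=0.0, k=3)
print(len(cands.co_up_genes), "co-up-regulated,",
      len(cands.retained_genes), "enhanced in CD")
# 266 co-up-regulated, 90 enhanced in CD
```

The same pipeline runs from the shell:

```sh
stressmodes run --simulate --seed 7 --out-dir out/      # full pipeline
stressmodes de --counts counts.tsv --design design.tsv --out-dir results/
stressmodes modes --de-dir results/ --top-n 500,1000,2000 --out modes.tsv
```

`run` writes one TSV per stage (DE tables, mode assignments, Venn cells,
candidates) plus a machine-readable `report.json` whose every number is
re-derivable from the stage TSVs.

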