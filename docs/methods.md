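# Methods

## The analysis in one paragraph

Given gene-level counts for a control (CK) and three stress treatments
(cold CT, drought DT, combined CD), the package estimates per-gene log₂
fold changes and adjusted p-values for each treatment against control,
discretizes each gene's response triple into a sign pattern, maps patterns
to transcriptional response modes, and derives set-level statistics (Venn
decompositions, overlap percentages, cumulative fold-change contributions)
and a candidate-gene list for combined-stress resistance. A planted-truth
simulator provides ground truth for every stage.

## Differential expression engine

The engine is a deliberately minimal NB workflow, chosen so that every
step has a closed form that tests can verify independently:

- **Size factors** — median-of-ratios: for genes expressed in all samples,
  factor *s<sub>j</sub>* = median over genes of count<sub>gj</sub> /
  geometric-mean<sub>g</sub>. Agrees with the reference DESeq2
  implementation to 1e-8 on test fixtures.
- **Dispersion** — pooled within-condition method of moments on normalized
  counts: φ̂ = max(floor, Σ<sub>c</sub>(n<sub>c</sub>−1)(v<sub>c</sub> −
  m<sub>c</sub>) / Σ<sub>c</sub>(n<sub>c</sub>−1)m<sub>c</sub>²), floor
  1e-8. There is **no shrinkage across genes**: at 3 replicates the
  per-gene estimate is noisy, which mainly costs power, and it keeps the
  estimator analytically checkable. Calibration: at 50 replicates the
  estimate lands in [0.05, 0.2] for true φ = 0.1.
- **Wald test** — *L* = log₂((m̄ₜ + c)/(m̄₀ + c)) with pseudo-count
  c = 0.5 (configurable) so zero-count groups stay finite. The standard
  error comes from the delta method with Var(normalized obs in sample j) ≈
  m/s<sub>j</sub> + φm²; two-sided normal p-values; genes with zero counts
  in both groups get L = 0, p = 1. Null simulations at 60 replicates pass
  a Kolmogorov–Smirnov uniformity check; at 3 replicates raw p-values are
  mildly liberal (~6% below 0.05) but the complete-null BH call rate stays
  around 1%, well inside the nominal 5%.
- **Multiple testing** — Benjamini–Hochberg within each contrast
  (delegated to `statsmodels.stats.multitest`; the test suite cross-checks
  it against a hand-coded step-up rule). A DEG is *q* < α = 0.05 with no
  fold-change threshold and no independent filtering — significance alone
  defines the sets that all downstream statistics consume.

This is a stand-in for a full DESeq-style analysis: no GLM covariates, no
dispersion shrinkage, no shrunken fold changes. The downstream mode and
set analyses only consume (L, q), so any engine producing those could be
substituted.

## Profiles and response modes

All 26 non-null sign patterns over (CT, DT, CD) are enumerated as
profiles 1–26 (lexicographic, +1 before 0 before −1, so profile 1 is
(+,+,+)). Modes are assigned by ordered rules, first match wins:

1. **similar** — s_CT = s_DT = s_CD ≠ 0 (2 profiles)
2. **prioritized** — s_CT = −s_DT ≠ 0 and s_CD ≠ 0 (4)
3. **canceled** — responds to a single stress, s_CD = 0 (8)
4. **independent** — exactly one single-stress response, carried to CD
   with the same sign (4)
5. **combinatorial** — everything else, including CD-only responders (8)

CD-only patterns (0,0,±1) are classed combinatorial because they are
interaction products invisible to single-stress experiments. The 26-profile
enumeration is this package's canonical scheme; published 20-profile
variants are subsets of it, and profile numbering is not comparable across
schemes — only the mode level is.

Discretization is significance-gated: s_X = sign(L_X) if q_X < α else 0,
matching the DEG definition. An alternative correlation-to-template
assignment (cosine similarity of the L vector to the template sign vector,
gated on at least one significant contrast) is available via
`assignment_method="correlation"` for sensitivity analysis; discrete is
the default because it is exactly the DEG criterion applied coordinatewise.

Mode fractions are reported over assigned (non-null-pattern) genes. The
*unpredictable* aggregate is the exact count sum of prioritized +
combinatorial + canceled. Stability is assessed by recomputing fractions
on the union of per-contrast top-N gene sets (N ∈ {500, 1000, 2000} by
default; ranking by q ascending, ties by |L| descending, then gene id) and
reporting the maximum absolute fraction difference across modes and N
pairs.

## Set statistics

Venn decompositions are exact disjoint-cell counts over the significant
gene sets, computed overall and separately for up- and down-regulated
genes (a gene can be up in one contrast and down in another, so
directional cells are not nested in the overall ones region-by-region,
but per-set totals partition exactly). Percentages are rounded half-up
to the precision conventionally printed: one decimal for the triple /
CD-unique / single-carried-to-CD shares, integer for the directional
induced/repressed shares.

The cumulative contribution of a single stress is Σ|L_CD| over its top-N
most significant responders (N = 1000 by default). The absolute sum is
the primary statistic — it measures magnitude of impact on the combined
response regardless of direction — and the signed sum is reported
alongside.

## Candidate selection

Co-up-regulated genes (q < α and L > 0 in all three contrasts) are
retained when L_CD − L_CT > margin **and** L_CD − L_DT > margin. The
margin defaults to 0 (strict inequality): any stated threshold would be
arbitrary, so the package makes the weakest defensible choice and exposes
it as a parameter. Retained genes are subgrouped by agglomerative
hierarchical clustering (Euclidean distance on (L_CT, L_DT, L_CD),
average linkage) cut at k = 3 clusters, then relabeled 1..k by descending
mean L_CD so Group 1 is always the most CD-induced; the relabeling makes
the output deterministic and comparable across runs. Annotation coverage
is the percentage (one decimal) of retained genes absent from the
annotation table; genes missing from annotation tables are reported as
"unannotated", never an error, since incomplete annotation is the norm
for non-model species.

## Synthetic data

The simulator emulates the target study design: 4 conditions × 3
replicates, NB counts with var = μ + φμ². Defaults are the conditions the
analyses are exercised under throughout: 5000 genes, φ = 0.1 (a typical
bulk RNA-seq biological-replicate dispersion), baseline means log-normal
with median 100 counts (log-sd 1), a single planted effect magnitude
|L| = 2 (a clearly detectable 4-fold change at 3 replicates), and mode
composition similar 26% / independent 36% / canceled 28% / combinatorial
10% / prioritized 0% — the composition this kind of cold/drought
combination experiment produces, so recovery statistics are measured
under a realistic mode mixture. Per-mode gene counts use largest-remainder
apportionment so they match round(fraction × n) exactly; sign patterns are
drawn uniformly from each mode's profiles. Optional per-sample depth
factors (log-uniform in [0.5, 2]) exercise normalization; optional
Gaussian jitter on |L| (truncated at 0.1 so planted signs never flip)
breaks the single-magnitude assumption.

What the simulator does **not** model: gene-length or GC bias, count
outliers, correlated genes, batch effects, or mean-dependent dispersion
trends. Passing recovery tests therefore shows the pipeline's logic is
correct under its own model assumptions, not that the engine matches a
production DE tool on real data.

All randomness flows from one seed through independent child streams
(`default_rng([seed, k])`), so truth tables and count matrices are
bit-reproducible.

## Numerical and design choices

- Rounding of printed percentages is half-up (via `decimal`), not
  banker's.
- Top-N ranking ties break by |L| descending then gene id ascending —
  fully deterministic.
- Cluster relabeling ties (equal mean L_CD) keep the original cluster-id
  order via a stable sort.
- The pipeline report contains no wall-clock values, so identical
  config + seed reproduces every output byte-for-byte (the JSON manifest
  embeds output paths; determinism is checked modulo that field).
- Problem sizes in the test suite and acceptance script (up to 5000 genes,
  null-FDR at 20 × 2000 genes) are chosen so the full planted analysis
  runs in seconds while estimates sit well inside their sampling
  tolerances.

## Known limitations

- At 2 replicates the MoM dispersion is very noisy; 3+ replicates are the
  intended regime.
- The Wald test is asymptotic; at very low counts (group means ≲ 5) its
  p-values are unreliable, as for any NB Wald test without exact or
  shrinkage machinery.
- Mode assignment inherits the DEG threshold's false positives: a gene
  whose true pattern contains a 0 is misassigned when that contrast is a
  false discovery, which is the dominant error source in planted-mode
  recovery (~92% recovered at the default conditions).
- Exact DEG counts from any real experiment depend on the DE tool and
  version; the package's reproducible claims are the arithmetic identities
  and the simulation-based properties, not real-data DEG counts.
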