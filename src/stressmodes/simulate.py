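"""Negative-binomial count simulation with planted response modes.

Emulates the study design the pipeline targets: four conditions (CK
control, CT cold, DT drought, CD combined) with a small number of
biological replicates each, and per-gene transcriptional responses
planted as one of the five interaction modes.  Each gene g has a
baseline mean mu_g (log-normal across genes), a dispersion phi, and a
log2 fold change L_{g,X} for each treatment X whose sign pattern is
drawn uniformly from the profiles of its planted mode.  Counts are

    K_{gj} ~ NB(mean = mu_g * 2^{L_{g,X(j)}} * s_j,  var = mean + phi*mean^2)

with s_j an optional per-sample depth factor (default 1) and L = 0 under
CK.  phi = 0 degenerates to Poisson sampling.  Everything is
deterministic given the seed.

Default mode fractions follow the composition the mode analysis is
expected to recover in this system: similar 26%, independent 36%,
canceled 28%, combinatorial 10%, prioritized 0%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CONTROL, TREATMENTS, CountMatrix, Design
from .errors import ConfigError, ValidationError
from .modes import MODES, classify_pattern, templates_by_mode

NULL_MODE = "null"

DEFAULT_MODE_FRACTIONS = {
    "similar": 0.26,
    "independent": 0.36,
    "canceled": 0.28,
    "combinatorial": 0.10,
    "prioritized": 0.0,
}


@dataclass
class SimConfig:
    """Simulation parameters.

    n_genes : number of genes.
    replicates : biological replicates per condition (>= 2).
    mode_fractions : fraction of genes planted in each mode; fractions
        sum to <= 1 and the remainder are null genes (no response).
    effect_size : planted |log2 fold change| for every responding
        condition (log2 units).
    effect_jitter_sd : s.d. of optional Gaussian jitter added to the
        effect magnitude (truncated so the planted sign never flips).
    baseline_log_mean, baseline_log_sd : natural-log parameters of the
        log-normal baseline mean distribution (defaults give a median
        around 100 counts).
    dispersion : constant NB dispersion phi (var = mu + phi mu^2).
    depth_factors : "none" for unit depth, "loguniform" to draw
        per-sample factors from log-uniform(0.5, 2) and exercise the
        normalization stage.
    rng_seed : master seed; truth construction and count sampling use
        independent child streams.
    """

    n_genes: int = 5000
    replicates: int = 3
    mode_fractions: dict = field(default_factory=lambda: dict(DEFAULT_MODE_FRACTIONS))
    effect_size: float = 2.0
    effect_jitter_sd: float = 0.0
    baseline_log_mean: float = float(np.log(100.0))
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    depth_factors: str = "none"
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        unknown = set(self.mode_fractions) - set(MODES)
        if unknown:
            raise ConfigError(f"unknown mode names in fractions: {sorted(unknown)}")
        fracs = list(self.mode_fractions.values())
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigError("mode fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ConfigError(f"mode fractions sum to {sum(fracs):.4f} > 1")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.dispersion < 0:
            raise ConfigError("dispersion phi must be >= 0")
        if self.depth_factors not in ("none", "loguniform"):
            raise ConfigError(f"unknown depth_factors mode {self.depth_factors!r}")


def _apportion(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n genes to modes.

    Each mode gets floor(fraction * n); leftover genes go to the modes
    with the largest fractional remainders (ties by mode order), so the
    totals always match round-off-free.
    """
    quotas = {m: fractions.get(m, 0.0) * n for m in MODES}
    counts = {m: int(np.floor(q)) for m, q in quotas.items()}
    target = int(round(sum(quotas.values())))
    leftover = target - sum(counts.values())
    remainders = sorted(
        MODES, key=lambda m: (-(quotas[m] - counts[m]), MODES.index(m))
    )
    for m in remainders[:leftover]:
        counts[m] += 1
    return counts


def build_truth(config: SimConfig) -> pd.DataFrame:
    """Construct the planted per-gene ground truth.

    Returns a DataFrame indexed by gene_id with the planted mode, sign
    pattern (s_ct, s_dt, s_cd), log2 fold changes (l_ct, l_dt, l_cd),
    baseline mean mu and dispersion phi.  Per-mode gene counts equal the
    largest-remainder apportionment of fraction * n_genes; sign patterns
    are drawn uniformly from the profiles of the planted mode; gene
    order is a seeded shuffle.
    """
    rng = np.random.default_rng([int(config.rng_seed), 0])
    counts = _apportion(config.mode_fractions, config.n_genes)
    by_mode = templates_by_mode()

    modes_col: list[str] = []
    patterns: list[tuple[int, int, int]] = []
    for mode in MODES:
        k = counts[mode]
        if k == 0:
            continue
        choices = by_mode[mode]
        idx = rng.integers(0, len(choices), size=k)
        modes_col.extend([mode] * k)
        patterns.extend(choices[i].pattern for i in idx)
    n_null = config.n_genes - len(modes_col)
    modes_col.extend([NULL_MODE] * n_null)
    patterns.extend([(0, 0, 0)] * n_null)

    order = rng.permutation(config.n_genes)
    modes_arr = np.array(modes_col, dtype=object)[order]
    signs = np.array(patterns, dtype=int)[order]

    magnitude = np.full((config.n_genes, 3), config.effect_size)
    if config.effect_jitter_sd > 0:
        jitter = rng.normal(0.0, config.effect_jitter_sd, size=magnitude.shape)
        magnitude = np.maximum(magnitude + jitter, 0.1)
    L = signs * magnitude

    mu = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes)
    width = len(str(config.n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(config.n_genes)]
    truth = pd.DataFrame(
        {
            "mode": modes_arr,
            "s_ct": signs[:, 0],
            "s_dt": signs[:, 1],
            "s_cd": signs[:, 2],
            "l_ct": L[:, 0],
            "l_dt": L[:, 1],
            "l_cd": L[:, 2],
            "mu": mu,
            "phi": config.dispersion,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    _check_truth(truth)
    return truth


def _check_truth(truth: pd.DataFrame) -> None:
    signs = truth[["s_ct", "s_dt", "s_cd"]].to_numpy()
    L = truth[["l_ct", "l_dt", "l_cd"]].to_numpy()
    if not np.array_equal(np.sign(L), signs):
        raise ValidationError("planted L inconsistent with planted sign pattern")
    for mode, s in zip(truth["mode"], signs):
        if mode == NULL_MODE:
            if tuple(s) != (0, 0, 0):
                raise ValidationError("null gene with non-null pattern")
        elif classify_pattern(tuple(s)) != mode:
            raise ValidationError(f"pattern {tuple(s)} inconsistent with mode {mode!r}")


def default_design(replicates: int) -> Design:
    """CK/CT/DT/CD design with the given replicates per condition."""
    mapping = {}
    for cond in (CONTROL,) + TREATMENTS:
        for r in range(1, replicates + 1):
            mapping[f"{cond}_{r}"] = cond
    return Design(mapping)


def simulate_counts(
    truth: pd.DataFrame,
    design: Design,
    config: SimConfig,
) -> CountMatrix:
    """Draw the NB count matrix for a planted truth table.

    The mean for gene g in sample j of condition X is
    mu_g * 2^{L_{g,X}} * depth_j; variance follows var = mu + phi mu^2.
    phi = 0 uses Poisson sampling.  Reproducible given the seed.
    """
    if (truth["phi"] < 0).any():
        raise ConfigError("dispersion phi must be >= 0")
    rng = np.random.default_rng([int(config.rng_seed), 1])
    samples = list(design.mapping)
    if config.depth_factors == "loguniform":
        depth = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(samples)))
    else:
        depth = np.ones(len(samples))

    mu = truth["mu"].to_numpy()
    phi = truth["phi"].to_numpy()
    l_cols = {"CT": "l_ct", "DT": "l_dt", "CD": "l_cd"}
    mat = np.zeros((len(truth), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        cond = design.mapping[sample]
        L = truth[l_cols[cond]].to_numpy() if cond != CONTROL else 0.0
        mean = mu * np.power(2.0, L) * depth[j]
        poisson = phi == 0
        col = np.empty(len(truth), dtype=np.int64)
        if poisson.any():
            col[poisson] = rng.poisson(mean[poisson])
        if (~poisson).any():
            size = 1.0 / phi[~poisson]
            p = size / (size + mean[~poisson])
            col[~poisson] = rng.negative_binomial(size, p)
        mat[:, j] = col
    df = pd.DataFrame(mat, index=truth.index, columns=samples)
    return CountMatrix(df)


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: (truth, design, counts) from one config."""
    truth = build_truth(config)
    design = default_design(config.replicates)
    counts = simulate_counts(truth, design, config)
    return truth, design, counts
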