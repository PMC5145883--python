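"""Model/Results interface for the combined-stress interaction analysis.

:class:`StressResponseModel` is built from a count matrix and a design;
``fit()`` runs normalization, dispersion estimation and the per-contrast
Wald tests and returns a :class:`StressResponseResults` carrying the
per-gene estimates, their standard errors and adjusted p-values.  All
downstream analyses — transcriptional response modes, Venn/overlap
statistics, cumulative contribution and candidate selection — are
methods of the results object, so a complete analysis reads::

    model = StressResponseModel(counts, design)
    res = model.fit(alpha=0.05)
    print(res.summary())
    modes = res.mode_summary(top_n=500)
    stats = res.overlap_statistics()
    cands = res.candidates(margin=0.0, k=3)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import candidates as _candidates
from . import de as _de
from . import modes as _modes
from . import sets as _sets
from .data import (
    CONTROL,
    TREATMENTS,
    AnnotationTable,
    CountMatrix,
    Design,
    PipelineConfig,
    read_counts,
    write_table,
)
from .errors import ValidationError


class StressResponseModel:
    """Negative-binomial differential-expression model of a 4-condition
    stress experiment (CK control; CT, DT, CD treatments).

    Parameters
    ----------
    counts : CountMatrix
        Raw gene-level integer counts.
    design : Design
        Sample-to-condition map; CK plus at least one treatment, >= 2
        replicates each.
    config : PipelineConfig, optional
        Analysis defaults (alpha, pseudo-count, dispersion floor, ...).
    """

    def __init__(self, counts: CountMatrix, design: Design,
                 config: PipelineConfig | None = None):
        design.validate_against(counts)
        self.counts = counts
        self.design = design
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(cls, counts_df: pd.DataFrame, design_mapping,
                       config: PipelineConfig | None = None) -> "StressResponseModel":
        """Build from a genes x samples DataFrame and a sample→condition map."""
        design = design_mapping if isinstance(design_mapping, Design) else Design(design_mapping)
        return cls(CountMatrix(counts_df), design, config=config)

    @classmethod
    def from_files(cls, counts_path, design_path,
                   config: PipelineConfig | None = None) -> "StressResponseModel":
        """Build from a counts TSV and a two-column design TSV."""
        config = config or PipelineConfig()
        counts, design = read_counts(counts_path, design_path,
                                     aliases=config.condition_aliases)
        return cls(counts, design, config=config)

    @property
    def treatments(self) -> list[str]:
        return [c for c in self.design.conditions if c != CONTROL]

    def fit(self, alpha: float | None = None) -> "StressResponseResults":
        """Estimate size factors and dispersions, test every treatment
        against CK, and BH-adjust within each contrast."""
        cfg = self.config
        alpha = cfg.alpha if alpha is None else alpha
        size_factors = _de.estimate_size_factors(self.counts)
        dispersions = _de.estimate_dispersion(
            self.counts, size_factors, self.design, floor=cfg.dispersion_floor
        )
        contrasts = {}
        for treatment in self.treatments:
            contrasts[treatment] = _de.test_contrast(
                self.counts,
                self.design,
                treatment,
                alpha=alpha,
                pseudocount=cfg.pseudocount,
                size_factors=size_factors,
                dispersions=dispersions,
            )
        return StressResponseResults(
            model=self,
            alpha=alpha,
            size_factors=size_factors,
            dispersions=dispersions,
            contrasts=contrasts,
        )


class StressResponseResults:
    """Fitted per-gene estimates and the downstream interaction analyses.

    Attributes
    ----------
    contrasts : dict of contrast name → DataFrame with columns
        (log2fc, se, pvalue, qvalue, significant, direction), indexed by
        gene.
    size_factors : per-sample normalization factors.
    dispersions : per-gene NB dispersion estimates.
    alpha : the adjusted-p significance threshold used.
    """

    def __init__(self, model, alpha, size_factors, dispersions, contrasts):
        self.model = model
        self.alpha = alpha
        self.size_factors = size_factors
        self.dispersions = dispersions
        self.contrasts = contrasts

    # -- basic accessors ----------------------------------------------------

    def de_table(self, contrast: str) -> pd.DataFrame:
        try:
            return self.contrasts[contrast]
        except KeyError:
            raise ValidationError(
                f"no fitted contrast {contrast!r}; available: {sorted(self.contrasts)}"
            ) from None

    def significant_genes(self, contrast: str, direction: str | None = None) -> set:
        table = self.de_table(contrast)
        mask = table["significant"].astype(bool)
        if direction is not None:
            mask &= table["direction"] == direction
        return set(table.index[mask])

    def _require_all_treatments(self):
        missing = [t for t in TREATMENTS if t not in self.contrasts]
        if missing:
            raise ValidationError(
                f"analysis needs all three contrasts; missing {missing}"
            )

    # -- response modes -----------------------------------------------------

    def profile_assignments(self, genes=None, method: str | None = None) -> pd.DataFrame:
        """Per-gene profile and response-mode assignment."""
        self._require_all_treatments()
        method = method or self.model.config.assignment_method
        return _modes.assign_profiles(self.contrasts, self.alpha, genes=genes, method=method)

    def top_n_genes(self, n: int) -> set:
        self._require_all_treatments()
        return _modes.select_top_n(self.contrasts, n)

    def mode_summary(self, top_n: int | None = None, method: str | None = None) -> _modes.ModeSummary:
        """Mode composition, over all genes or the top-N significant union."""
        genes = sorted(self.top_n_genes(top_n)) if top_n is not None else None
        return _modes.summarize_modes(self.profile_assignments(genes=genes, method=method))

    def stability(self, n_list=None, method: str | None = None) -> _modes.StabilityResult:
        self._require_all_treatments()
        n_list = n_list or self.model.config.top_n_list
        method = method or self.model.config.assignment_method
        return _modes.stability_check(self.contrasts, n_list, self.alpha, method=method)

    # -- set algebra --------------------------------------------------------

    def venn(self, direction: str | None = None) -> _sets.VennDecomposition:
        """Venn decomposition of DEG sets (all, or 'up'/'down' only)."""
        self._require_all_treatments()
        sets_ = _sets.sig_gene_sets(self.contrasts, direction=direction)
        return _sets.venn_counts(sets_["CT"], sets_["DT"], sets_["CD"])

    def overlap_statistics(self) -> dict:
        return _sets.overlap_statistics(
            self.venn(), up=self.venn("up"), down=self.venn("down")
        )

    def contribution(self, stress: str, n: int | None = None) -> _sets.ContributionStat:
        """Cumulative |log2FC in CD| of the top-n responders to one stress."""
        self._require_all_treatments()
        if stress not in ("CT", "DT"):
            raise ValidationError("contribution is defined for the single stresses CT and DT")
        n = n or self.model.config.contribution_n
        ranked = _modes.rank_by_significance(self.de_table(stress))
        return _sets.cumulative_contribution(ranked[:n], self.de_table("CD"), stress=stress)

    # -- candidates ---------------------------------------------------------

    def candidates(
        self,
        margin: float | None = None,
        k: int | None = None,
        annotations: AnnotationTable | None = None,
    ) -> _candidates.CandidateSet:
        """Co-up-regulated genes filtered for enhanced CD expression and
        subgrouped; annotation columns added when a table is supplied."""
        self._require_all_treatments()
        cfg = self.model.config
        margin = cfg.enhancement_margin if margin is None else margin
        k = cfg.subgroup_k if k is None else k
        co_up = _candidates.co_upregulated(self.contrasts, self.alpha)
        cset = _candidates.enhanced_in_combined(co_up, self.contrasts, margin=margin)
        if len(cset.retained_genes) >= k:
            cset = _candidates.cluster_subgroups(cset, k)
        if annotations is not None:
            table = cset.table.copy()
            table["annotation"] = [annotations.annotation(g) for g in table.index]
            table["effect"] = [annotations.effect(g) for g in table.index]
            cset = _candidates.CandidateSet(table=table, margin=cset.margin)
        return cset

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fit: design, normalization, DEG counts."""
        lines = []
        width = 64
        lines.append("Combined-Stress Response Model".center(width))
        lines.append("=" * width)
        n_genes, n_samples = self.model.counts.shape
        lines.append(f"{'No. genes:':<28}{n_genes:>10}")
        lines.append(f"{'No. samples:':<28}{n_samples:>10}")
        for cond in self.model.design.conditions:
            lines.append(f"{'  replicates ' + cond + ':':<28}{len(self.model.design.samples(cond)):>10}")
        lines.append(f"{'Significance (adj. p):':<28}{self.alpha:>10g}")
        med_phi = float(self.dispersions.median())
        lines.append(f"{'Median dispersion:':<28}{med_phi:>10.4f}")
        lines.append("-" * width)
        lines.append(f"{'contrast':<12}{'DEGs':>8}{'up':>8}{'down':>8}{'median |L|':>14}")
        for name, table in self.contrasts.items():
            sig = table[table["significant"]]
            med_l = float(sig["log2fc"].abs().median()) if len(sig) else float("nan")
            lines.append(
                f"{name + ' vs CK':<12}{len(sig):>8}"
                f"{int((sig['direction'] == 'up').sum()):>8}"
                f"{int((sig['direction'] == 'down').sum()):>8}"
                f"{med_l:>14.3f}"
            )
        lines.append("=" * width)
        return "\n".join(lines)

    def to_files(self, out_dir) -> dict:
        """Write one DE TSV per contrast; returns the file manifest."""
        out_dir = Path(out_dir)
        manifest = {}
        for name, table in self.contrasts.items():
            path = out_dir / f"de_{name}.tsv"
            write_table(table.reset_index(), path)
            manifest[f"de_{name}"] = str(path)
        return manifest
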