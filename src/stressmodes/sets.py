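"""DEG set algebra: three-way Venn decomposition, overlap percentages,
and the cumulative log-fold-change contribution statistic.

The overlap statistics quantify how predictable the combined-stress
(CD) transcriptome is from the single stresses: the share of DEGs
common to all three treatments, the CD-unique share, how many
single-stress DEGs carry over to CD, and — separately for induced and
repressed genes — how many genes responding to at least one single
stress respond the same way under the combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Venn region names: tuple order is (CT, DT, CD) membership
REGIONS = ("ct_only", "dt_only", "cd_only", "ct_dt", "ct_cd", "dt_cd", "ct_dt_cd")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, the convention of printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class VennDecomposition:
    """Disjoint cell counts of three DEG sets over (CT, DT, CD)."""

    ct_only: int
    dt_only: int
    cd_only: int
    ct_dt: int
    ct_cd: int
    dt_cd: int
    ct_dt_cd: int

    def __post_init__(self):
        for name in REGIONS:
            if getattr(self, name) < 0:
                raise ValidationError(f"negative Venn cell {name}")

    @property
    def union_size(self) -> int:
        return sum(getattr(self, r) for r in REGIONS)

    @property
    def ct_total(self) -> int:
        return self.ct_only + self.ct_dt + self.ct_cd + self.ct_dt_cd

    @property
    def dt_total(self) -> int:
        return self.dt_only + self.ct_dt + self.dt_cd + self.ct_dt_cd

    @property
    def cd_total(self) -> int:
        return self.cd_only + self.ct_cd + self.dt_cd + self.ct_dt_cd

    @property
    def single_union(self) -> int:
        """Genes in CT or DT (at least one single stress)."""
        return self.ct_only + self.dt_only + self.ct_dt + self.ct_cd + self.dt_cd + self.ct_dt_cd

    @property
    def single_and_cd(self) -> int:
        """Genes in (CT union DT) that are also in CD."""
        return self.ct_cd + self.dt_cd + self.ct_dt_cd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": REGIONS, "count": [getattr(self, r) for r in REGIONS]}
        )


def venn_counts(ct_set, dt_set, cd_set) -> VennDecomposition:
    """Exact disjoint-cell counts for three gene sets."""
    ct, dt, cd = set(ct_set), set(dt_set), set(cd_set)
    triple = ct & dt & cd
    return VennDecomposition(
        ct_only=len(ct - dt - cd),
        dt_only=len(dt - ct - cd),
        cd_only=len(cd - ct - dt),
        ct_dt=len((ct & dt) - cd),
        ct_cd=len((ct & cd) - dt),
        dt_cd=len((dt & cd) - ct),
        ct_dt_cd=len(triple),
    )


def sig_gene_sets(de_tables: dict[str, pd.DataFrame], direction: str | None = None):
    """Significant gene sets per contrast, optionally restricted to a direction."""
    out = {}
    for name, table in de_tables.items():
        mask = table["significant"].astype(bool)
        if direction is not None:
            mask &= table["direction"] == direction
        out[name] = set(table.index[mask])
    return out


def overlap_statistics(
    venn: VennDecomposition,
    up: VennDecomposition | None = None,
    down: VennDecomposition | None = None,
) -> dict:
    """Derived overlap percentages, rounded as conventionally printed.

    From the all-DEG decomposition: the triple intersection as % of the
    union (one decimal), the CD-unique count as % of the CD total (one
    decimal), and |(CT u DT) n CD| as % of the union (one decimal).
    From the up/down decompositions (when given): among genes
    induced (repressed) by at least one single stress, the count and
    integer % also induced (repressed) in CD.
    """
    if venn.union_size == 0:
        raise ValidationError("empty DEG union: percentages undefined")
    stats = {
        "union_size": venn.union_size,
        "ct_total": venn.ct_total,
        "dt_total": venn.dt_total,
        "cd_total": venn.cd_total,
        "triple_count": venn.ct_dt_cd,
        "triple_pct": round_half_up(100.0 * venn.ct_dt_cd / venn.union_size, 1),
        "cd_unique_count": venn.cd_only,
        "single_in_cd_count": venn.single_and_cd,
        "single_in_cd_pct": round_half_up(100.0 * venn.single_and_cd / venn.union_size, 1),
    }
    if venn.cd_total > 0:
        stats["cd_unique_pct"] = round_half_up(100.0 * venn.cd_only / venn.cd_total, 1)
    for label, dec in (("induced", up), ("repressed", down)):
        if dec is None:
            continue
        single = dec.single_union
        both = dec.single_and_cd
        stats[f"{label}_single_count"] = single
        stats[f"{label}_also_cd_count"] = both
        if single > 0:
            stats[f"{label}_also_cd_pct"] = round_half_up(100.0 * both / single, 0)
    return stats


@dataclass
class ContributionStat:
    """Cumulative CD log2-fold-change contribution of one single stress.

    ``absolute`` (the primary statistic) sums |log2FC in CD| over the
    top-N most significant responders to that stress; ``signed`` is the
    plain sum, reported alongside.
    """

    stress: str
    genes: list
    absolute: float
    signed: float
    n_missing: int


def cumulative_contribution(
    top_genes,
    de_cd: pd.DataFrame,
    stress: str = "",
) -> ContributionStat:
    """Sum of |log2FC in CD| over a single-stress top-gene list.

    Genes absent from the CD table contribute 0 and are logged; an empty
    list yields contribution 0 with a warning.
    """
    genes = list(top_genes)
    if not genes:
        logger.warning("empty gene list for contribution of %s; contribution is 0", stress)
        return ContributionStat(stress, [], 0.0, 0.0, 0)
    present = [g for g in genes if g in de_cd.index]
    missing = len(genes) - len(present)
    if missing:
        logger.warning("%d of %d genes absent from the CD contrast; they contribute 0",
                       missing, len(genes))
    l_cd = de_cd.loc[present, "log2fc"].to_numpy(dtype=float)
    return ContributionStat(
        stress=stress,
        genes=genes,
        absolute=float(np.abs(l_cd).sum()),
        signed=float(l_cd.sum()),
        n_missing=missing,
    )
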