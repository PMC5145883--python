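"""Candidate genes for combined-stress resistance.

The selection mirrors the rationale that under a resource-limited
combined stress a plant induces only its most effective genes: start
from genes significantly up-regulated under all three treatments
(co-up-regulated), keep those whose combined-stress induction exceeds
both single-stress inductions (enhanced in CD), subgroup the survivors
by hierarchical clustering of their fold-change vectors, and join with
annotation/effect tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data import AnnotationTable
from .errors import ValidationError
from .modes import UNASSIGNED, profile_by_id
from .sets import round_half_up


def co_upregulated(de_tables: dict[str, pd.DataFrame], alpha: float) -> list:
    """Genes with q < alpha and log2FC > 0 in CT, DT and CD alike."""
    sets = []
    for key in ("CT", "DT", "CD"):
        if key not in de_tables:
            raise ValidationError(f"missing DE contrast {key!r}")
        t = de_tables[key]
        sets.append(set(t.index[(t["qvalue"] < alpha) & (t["log2fc"] > 0)]))
    return sorted(sets[0] & sets[1] & sets[2])


@dataclass
class CandidateSet:
    """Co-up-regulated genes with the enhanced-in-CD filter applied.

    ``table`` is indexed by gene with the three log2 fold changes, the
    enhancement deltas (l_cd - l_ct, l_cd - l_dt), the retained flag and
    (after clustering / annotation) subgroup and annotation columns.
    """

    table: pd.DataFrame
    margin: float

    @property
    def co_up_genes(self) -> list:
        return list(self.table.index)

    @property
    def retained_genes(self) -> list:
        return list(self.table.index[self.table["retained"]])

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]


def enhanced_in_combined(
    candidates,
    de_tables: dict[str, pd.DataFrame],
    margin: float = 0.0,
) -> CandidateSet:
    """Retain genes whose CD fold change exceeds both single-stress ones.

    A gene is retained when (l_cd - l_ct) > margin and
    (l_cd - l_dt) > margin, margin in log2 units (default 0: strictly
    more enhanced under the combination).
    """
    if margin < 0:
        raise ValidationError("enhancement margin must be >= 0")
    genes = list(candidates)
    for key in ("CT", "DT", "CD"):
        missing = set(genes) - set(de_tables[key].index)
        if missing:
            raise ValidationError(
                f"candidate genes absent from contrast {key!r}: {sorted(missing)[:5]}"
            )
    l_ct = de_tables["CT"].loc[genes, "log2fc"].to_numpy(dtype=float)
    l_dt = de_tables["DT"].loc[genes, "log2fc"].to_numpy(dtype=float)
    l_cd = de_tables["CD"].loc[genes, "log2fc"].to_numpy(dtype=float)
    d_ct = l_cd - l_ct
    d_dt = l_cd - l_dt
    table = pd.DataFrame(
        {
            "l_ct": l_ct,
            "l_dt": l_dt,
            "l_cd": l_cd,
            "delta_cd_ct": d_ct,
            "delta_cd_dt": d_dt,
            "retained": (d_ct > margin) & (d_dt > margin),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return CandidateSet(table=table, margin=margin)


def cluster_subgroups(candidate_set: CandidateSet, k: int) -> CandidateSet:
    """Split retained genes into k expression subgroups.

    Agglomerative hierarchical clustering (Euclidean distance on the
    (l_ct, l_dt, l_cd) vectors, average linkage) cut at k clusters;
    cluster labels are renumbered 1..k by descending mean l_cd so Group 1
    always has the highest combined-stress induction.  Deterministic.
    """
    retained = candidate_set.retained
    if len(retained) < k:
        raise ValidationError(
            f"only {len(retained)} retained genes but k={k}; choose a smaller k"
        )
    vectors = retained[["l_ct", "l_dt", "l_cd"]].to_numpy(dtype=float)
    if k == 1 or len(retained) == 1:
        raw = np.ones(len(retained), dtype=int)
    else:
        link = hierarchy.linkage(pdist(vectors), method="average")
        raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    means = pd.Series(retained["l_cd"].to_numpy(), index=raw).groupby(level=0).mean()
    order = means.sort_values(ascending=False, kind="mergesort").index  # ties keep cluster-id order
    relabel = {old: new for new, old in enumerate(order, start=1)}
    labels = pd.Series([relabel[r] for r in raw], index=retained.index)
    table = candidate_set.table.copy()
    table["subgroup"] = labels.reindex(table.index).astype("Int64")
    return CandidateSet(table=table, margin=candidate_set.margin)


def annotation_coverage(candidate_set: CandidateSet, ann: AnnotationTable) -> dict:
    """Count and percentage (one decimal) of retained genes lacking annotation."""
    genes = candidate_set.retained_genes
    if not genes:
        raise ValidationError("no retained genes: unannotated fraction undefined")
    unannotated = [g for g in genes if not ann.is_annotated(g)]
    return {
        "n_retained": len(genes),
        "n_unannotated": len(unannotated),
        "unannotated_pct": round_half_up(100.0 * len(unannotated) / len(genes), 1),
    }


def select_by_modes_and_effect(
    assignments: pd.DataFrame,
    profile_ids,
    effects: AnnotationTable,
) -> dict[str, list]:
    """Genes in the given profiles, partitioned by senescence-effect label.

    ``profile_ids`` index this package's canonical 26-profile
    enumeration; unknown ids raise.  Output keys are "promote", "delay"
    and "unlabeled".
    """
    profile_ids = {int(p) for p in profile_ids}
    for pid in profile_ids:
        profile_by_id(pid)  # raises on unknown id
    selected = assignments[
        (assignments["meta_mode"] != UNASSIGNED)
        & assignments["profile_id"].isin(profile_ids)
    ]
    out: dict[str, list] = {"promote": [], "delay": [], "unlabeled": []}
    for gene in selected.index:
        out[effects.effect(gene)].append(gene)
    return out
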