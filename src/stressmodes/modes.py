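"""Predefined expression profiles and transcriptional response modes.

A gene's response to cold (CT), drought (DT) and their combination (CD),
relative to the unstressed control, is discretized to a sign pattern
(s_CT, s_DT, s_CD) with s in {-1, 0, +1}.  Each of the 26 non-null
patterns is one *profile*; profiles aggregate into five interaction
*modes* describing how the combined-stress response relates to the
single-stress responses:

similar
    the gene responds the same way under CT, DT and CD.
prioritized
    opposing responses to CT and DT, and the combined response follows
    one of them (an antagonistic interaction resolved under CD).
canceled
    a single-stress response that returns to control level under the
    combined treatment.
independent
    a response to exactly one single stress that carries over unchanged
    to the combined treatment.
combinatorial
    everything else — novel behaviour emerging only from the stress
    combination, including CD-only responders.

The "prioritized", "combinatorial" and "canceled" modes together form
the *unpredictable* aggregate: genes whose combined-stress behaviour
cannot be inferred from the single-stress experiments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

MODES = ("similar", "independent", "combinatorial", "canceled", "prioritized")
UNPREDICTABLE = ("prioritized", "combinatorial", "canceled")
UNASSIGNED = "unassigned"

Pattern = tuple[int, int, int]


@dataclass(frozen=True)
class ProfileTemplate:
    """One predefined expression profile: a sign pattern and its mode."""

    profile_id: int
    pattern: Pattern
    meta_mode: str


def classify_pattern(pattern: Pattern) -> str:
    """Assign a non-null sign pattern to its response mode.

    Rules are applied in order; the first match wins:

    1. similar: s_CT == s_DT == s_CD != 0
    2. prioritized: s_CT == -s_DT != 0 and s_CD != 0
    3. canceled: (s_CT != 0 or s_DT != 0) and s_CD == 0
    4. independent: exactly one of s_CT, s_DT nonzero and s_CD equal to it
    5. combinatorial: every remaining pattern
    """
    s_ct, s_dt, s_cd = pattern
    if any(s not in (-1, 0, 1) for s in pattern):
        raise ValidationError(f"sign pattern entries must be in {{-1,0,1}}: {pattern}")
    if pattern == (0, 0, 0):
        raise ValidationError("the null pattern (0,0,0) has no mode")
    if s_ct == s_dt == s_cd:
        return "similar"
    if s_ct == -s_dt != 0 and s_cd != 0:
        return "prioritized"
    if s_cd == 0:
        return "canceled"
    if (s_ct != 0) != (s_dt != 0) and s_cd == (s_ct or s_dt):
        return "independent"
    return "combinatorial"


def build_profile_templates() -> list[ProfileTemplate]:
    """Enumerate all 26 non-null sign patterns as profiles 1..26.

    Patterns are ordered lexicographically over (s_CT, s_DT, s_CD) with
    +1 before 0 before -1, so profile 1 is (+1,+1,+1) and profile 26 is
    (-1,-1,-1).  The profile/mode map is a partition: every non-null
    pattern belongs to exactly one profile and one mode.
    """
    templates = []
    pid = 0
    for pattern in itertools.product((1, 0, -1), repeat=3):
        if pattern == (0, 0, 0):
            continue
        pid += 1
        templates.append(ProfileTemplate(pid, pattern, classify_pattern(pattern)))
    return templates


def templates_by_mode() -> dict[str, list[ProfileTemplate]]:
    out: dict[str, list[ProfileTemplate]] = {m: [] for m in MODES}
    for t in build_profile_templates():
        out[t.meta_mode].append(t)
    return out


_PATTERN_TO_TEMPLATE = {t.pattern: t for t in build_profile_templates()}
_ID_TO_TEMPLATE = {t.profile_id: t for t in build_profile_templates()}


def profile_for_pattern(pattern: Pattern) -> ProfileTemplate:
    try:
        return _PATTERN_TO_TEMPLATE[tuple(pattern)]
    except KeyError:
        raise ValidationError(f"no profile for pattern {pattern}") from None


def profile_by_id(profile_id: int) -> ProfileTemplate:
    try:
        return _ID_TO_TEMPLATE[int(profile_id)]
    except (KeyError, ValueError):
        raise ValidationError(f"unknown profile id {profile_id!r}") from None


# ---------------------------------------------------------------------------
# Discretization and assignment
# ---------------------------------------------------------------------------

def discretize(l_values, q_values, alpha: float) -> Pattern:
    """Significance-gated sign pattern for one gene.

    s_X = sign(L_X) if q_X < alpha else 0, over (CT, DT, CD).
    """
    l_values = np.asarray(l_values, dtype=float)
    q_values = np.asarray(q_values, dtype=float)
    if l_values.shape != (3,) or q_values.shape != (3,):
        raise ValidationError("discretize expects (L, q) triples over (CT, DT, CD)")
    signs = np.where(q_values < alpha, np.sign(l_values), 0).astype(int)
    return tuple(signs)


def assign_profiles(
    de_tables: dict[str, pd.DataFrame],
    alpha: float,
    genes=None,
    method: str = "discrete",
) -> pd.DataFrame:
    """Assign genes to profiles and modes from the three DE contrasts.

    Parameters
    ----------
    de_tables : mapping of contrast name ("CT", "DT", "CD") to a DE table
        indexed by gene with columns ``log2fc`` and ``qvalue``.
    alpha : significance gate for discretization.
    genes : optional iterable restricting the assignment; default all
        genes shared by the three contrasts.
    method : "discrete" assigns by the significance-gated sign pattern;
        "correlation" assigns significance-gated genes to the template
        whose sign vector has the highest cosine similarity with the
        gene's log2FC vector (ties broken by lowest profile id).

    Returns a DataFrame indexed by gene with columns s_ct, s_dt, s_cd,
    l_ct, l_dt, l_cd, q_ct, q_dt, q_cd, profile_id, meta_mode.  Genes
    whose pattern is all-null get profile_id 0 and meta_mode
    "unassigned"; they are excluded from mode fractions downstream.
    """
    for key in ("CT", "DT", "CD"):
        if key not in de_tables:
            raise ValidationError(f"missing DE contrast {key!r}")
    index = de_tables["CT"].index
    for key in ("DT", "CD"):
        if not index.equals(de_tables[key].index):
            common = index.intersection(de_tables[key].index)
            missing = index.difference(de_tables[key].index)
            if len(missing):
                raise ValidationError(
                    f"gene {missing[0]!r} missing from contrast {key!r}"
                )
            index = common
    if genes is not None:
        genes = [g for g in genes]
        missing = set(genes) - set(index)
        if missing:
            raise ValidationError(f"genes absent from DE tables: {sorted(missing)[:5]}")
        index = pd.Index(genes)

    L = np.column_stack([de_tables[c].loc[index, "log2fc"].to_numpy() for c in ("CT", "DT", "CD")])
    Q = np.column_stack([de_tables[c].loc[index, "qvalue"].to_numpy() for c in ("CT", "DT", "CD")])
    gated = np.where(Q < alpha, np.sign(L), 0).astype(int)

    if method == "discrete":
        signs = gated
    elif method == "correlation":
        signs = _correlation_assign(L, gated)
    else:
        raise ValidationError(f"unknown assignment method {method!r}")

    keys = signs[:, 0] * 9 + signs[:, 1] * 3 + signs[:, 2]
    pid_lookup = np.zeros(27, dtype=int)
    mode_lookup = np.empty(27, dtype=object)
    mode_lookup[:] = UNASSIGNED
    for t in build_profile_templates():
        k = t.pattern[0] * 9 + t.pattern[1] * 3 + t.pattern[2]
        pid_lookup[k % 27] = t.profile_id
        mode_lookup[k % 27] = t.meta_mode

    out = pd.DataFrame(
        {
            "s_ct": signs[:, 0],
            "s_dt": signs[:, 1],
            "s_cd": signs[:, 2],
            "l_ct": L[:, 0],
            "l_dt": L[:, 1],
            "l_cd": L[:, 2],
            "q_ct": Q[:, 0],
            "q_dt": Q[:, 1],
            "q_cd": Q[:, 2],
            "profile_id": pid_lookup[keys % 27],
            "meta_mode": mode_lookup[keys % 27],
        },
        index=index,
    )
    out.index.name = "gene_id"
    return out


def _correlation_assign(L: np.ndarray, gated: np.ndarray) -> np.ndarray:
    """Best-template assignment by cosine similarity on log2FC vectors.

    Genes with an all-null gated pattern remain unassigned; the rest are
    matched to the template sign vector most parallel to their L vector.
    """
    templates = build_profile_templates()
    T = np.array([t.pattern for t in templates], dtype=float)
    T_norm = T / np.linalg.norm(T, axis=1, keepdims=True)
    signs = np.zeros_like(gated)
    active = (gated != 0).any(axis=1)
    if active.any():
        La = L[active]
        norms = np.linalg.norm(La, axis=1)
        norms[norms == 0] = 1.0
        cos = (La / norms[:, None]) @ T_norm.T
        best = np.argmax(cos, axis=1)  # argmax takes the lowest index on ties
        signs[active] = np.array([templates[b].pattern for b in best], dtype=int)
    return signs


# ---------------------------------------------------------------------------
# Top-N selection, summaries, stability
# ---------------------------------------------------------------------------

def rank_by_significance(de_table: pd.DataFrame) -> pd.Index:
    """Genes ordered by q ascending, then |log2FC| descending, then id."""
    keys = pd.DataFrame(
        {
            "qvalue": de_table["qvalue"].to_numpy(),
            "neg_absl": -de_table["log2fc"].abs().to_numpy(),
            "gene": de_table.index.astype(str),
        },
        index=de_table.index,
    )
    return keys.sort_values(["qvalue", "neg_absl", "gene"], kind="mergesort").index


def select_top_n(de_tables: dict[str, pd.DataFrame], n: int) -> set:
    """Union of the top-n most significant genes from each contrast.

    Ranking: q ascending, ties by |log2FC| descending, then gene id
    ascending — fully deterministic.  If n exceeds the genes available
    in a contrast, all genes are taken and a warning is logged.
    """
    if n < 1:
        raise ValidationError(f"top-N must be >= 1, got {n}")
    union: set = set()
    for name, table in de_tables.items():
        if n > len(table):
            logger.warning(
                "top-N %d exceeds %d genes available in contrast %s; taking all",
                n, len(table), name,
            )
        ranked = rank_by_significance(table)
        union.update(ranked[:n])
    return union


@dataclass
class ModeSummary:
    """Gene counts and fractions per response mode over assigned genes."""

    counts: dict[str, int]
    fractions: dict[str, float]
    n_assigned: int

    @property
    def unpredictable_count(self) -> int:
        return sum(self.counts[m] for m in UNPREDICTABLE)

    @property
    def unpredictable_fraction(self) -> float:
        return sum(self.fractions[m] for m in UNPREDICTABLE)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"meta_mode": m, "count": self.counts[m], "fraction": self.fractions[m]}
            for m in MODES
        ]
        rows.append(
            {
                "meta_mode": "unpredictable",
                "count": self.unpredictable_count,
                "fraction": self.unpredictable_fraction,
            }
        )
        return pd.DataFrame(rows)


def summarize_modes(assignments: pd.DataFrame) -> ModeSummary:
    """Aggregate profile assignments into per-mode counts and fractions.

    Fractions are over assigned (non-null pattern) genes and sum to 1;
    the unpredictable aggregate is prioritized + combinatorial + canceled.
    """
    assigned = assignments[assignments["meta_mode"] != UNASSIGNED]
    if len(assigned) == 0:
        raise ValidationError("no assigned genes: every pattern was null")
    vc = assigned["meta_mode"].value_counts()
    counts = {m: int(vc.get(m, 0)) for m in MODES}
    total = len(assigned)
    fractions = {m: counts[m] / total for m in MODES}
    return ModeSummary(counts=counts, fractions=fractions, n_assigned=total)


def mode_summary_from_counts(counts: dict[str, int]) -> ModeSummary:
    """Build a ModeSummary directly from per-mode gene counts."""
    counts = {m: int(counts.get(m, 0)) for m in MODES}
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("no assigned genes in mode counts")
    return ModeSummary(counts=counts, fractions={m: c / total for m, c in counts.items()}, n_assigned=total)


@dataclass
class StabilityResult:
    """Mode fractions per top-N gene set and their maximum deviation."""

    summaries: dict[int, ModeSummary]
    max_deviation: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n, summ in sorted(self.summaries.items()):
            for m in MODES:
                rows.append({"top_n": n, "meta_mode": m, "count": summ.counts[m],
                             "fraction": summ.fractions[m]})
        return pd.DataFrame(rows)


def stability_check(
    de_tables: dict[str, pd.DataFrame],
    n_list,
    alpha: float,
    method: str = "discrete",
) -> StabilityResult:
    """Mode fractions across top-N gene sets and their max |difference|.

    For each N the union of per-contrast top-N genes is assigned to
    modes; the deviation is the maximum over modes and N pairs of the
    absolute fraction difference.  Stable assignments (deviation small)
    mean the mode composition does not depend on how many significant
    genes are considered.
    """
    n_list = list(n_list)
    if not n_list:
        raise ValidationError("n_list must be non-empty")
    summaries = {}
    for n in n_list:
        genes = sorted(select_top_n(de_tables, n))
        assignments = assign_profiles(de_tables, alpha, genes=genes, method=method)
        summaries[n] = summarize_modes(assignments)
    max_dev = 0.0
    ns = sorted(summaries)
    for i, a in enumerate(ns):
        for b in ns[i + 1:]:
            for m in MODES:
                dev = abs(summaries[a].fractions[m] - summaries[b].fractions[m])
                max_dev = max(max_dev, dev)
    return StabilityResult(summaries=summaries, max_deviation=max_dev)
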