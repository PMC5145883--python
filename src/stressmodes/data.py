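"""Shared data model and tabular I/O.

The pipeline starts at a gene-level count matrix (genes x samples,
non-negative integers) with a design table mapping each sample to one of
four conditions: CK (unstressed control), CT (cold), DT (drought) and CD
(combined cold + drought).  All interchange files are UTF-8
tab-separated text with "." as the decimal mark.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError, ValidationError

CONTROL = "CK"
TREATMENTS = ("CT", "DT", "CD")
CONDITIONS = (CONTROL,) + TREATMENTS

#: number of significant digits used when floats are written to TSV
FLOAT_DIGITS = 6


class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by unique gene ids, columns by unique sample ids;
        every entry a finite non-negative integer.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.isfinite(values).all():
                bad = np.argwhere(~np.isfinite(values))[0]
                raise ValidationError(
                    f"non-finite count for gene {counts.index[bad[0]]!r}, "
                    f"sample {counts.columns[bad[1]]!r}"
                )
            rounded = np.rint(values)
            if not np.array_equal(rounded, values):
                bad = np.argwhere(rounded != values)[0]
                raise ValidationError(
                    f"non-integer count for gene {counts.index[bad[0]]!r}, "
                    f"sample {counts.columns[bad[1]]!r}"
                )
            values = rounded.astype(np.int64)
            counts = pd.DataFrame(values, index=counts.index, columns=counts.columns)
        if values.size and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count for gene {counts.index[bad[0]]!r}, "
                f"sample {counts.columns[bad[1]]!r}"
            )
        self.counts = counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CountMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


class Design:
    """Sample-to-condition assignment over {CK, CT, DT, CD}.

    CK is mandatory; every condition present must have at least two
    replicates.  An ``aliases`` map renames incoming labels to the
    four-state vocabulary before validation.
    """

    def __init__(self, mapping: Mapping[str, str], aliases: Mapping[str, str] | None = None):
        aliases = dict(aliases or {})
        resolved = {}
        for sample, cond in mapping.items():
            cond = aliases.get(cond, cond)
            if cond not in CONDITIONS:
                raise ValidationError(
                    f"unknown condition {cond!r} for sample {sample!r}; "
                    f"expected one of {CONDITIONS}"
                )
            if sample in resolved:
                raise ValidationError(f"sample {sample!r} listed twice in design")
            resolved[sample] = cond
        counts = pd.Series(resolved).value_counts()
        if CONTROL not in counts:
            raise ValidationError("design has no control (CK) samples")
        if not any(t in counts for t in TREATMENTS):
            raise ValidationError("design has no treatment samples")
        few = [c for c, n in counts.items() if n < 2]
        if few:
            raise ValidationError(f"conditions with fewer than 2 replicates: {sorted(few)}")
        self.mapping = resolved

    @property
    def conditions(self) -> list[str]:
        return [c for c in CONDITIONS if c in set(self.mapping.values())]

    def samples(self, condition: str) -> list[str]:
        return [s for s, c in self.mapping.items() if c == condition]

    def validate_against(self, counts: CountMatrix) -> None:
        missing = [s for s in counts.sample_ids if s not in self.mapping]
        if missing:
            raise ValidationError(f"samples absent from design: {missing}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sizes = {c: len(self.samples(c)) for c in self.conditions}
        return f"Design({sizes})"


class AnnotationTable:
    """Optional per-gene free-text annotation and senescence-effect label.

    Genes absent from the table are reported as unannotated/unlabeled
    rather than raising, because real annotation tables never cover the
    whole transcriptome.
    """

    EFFECTS = ("promote", "delay")

    def __init__(
        self,
        annotations: Mapping[str, str] | None = None,
        effects: Mapping[str, str] | None = None,
    ):
        self.annotations = {g: a for g, a in (annotations or {}).items() if a}
        self.effects = {}
        for g, e in (effects or {}).items():
            if not e:
                continue
            if e not in self.EFFECTS:
                raise ValidationError(
                    f"unknown effect label {e!r} for gene {g!r}; expected one of {self.EFFECTS}"
                )
            self.effects[g] = e

    def annotation(self, gene_id: str) -> str:
        return self.annotations.get(gene_id, "unannotated")

    def is_annotated(self, gene_id: str) -> bool:
        return gene_id in self.annotations

    def effect(self, gene_id: str) -> str:
        return self.effects.get(gene_id, "unlabeled")


@dataclass
class PipelineConfig:
    """Tunable analysis parameters shared across stages.

    alpha : BH-adjusted p-value threshold defining a DEG (default 0.05,
        the criterion the differential-expression stage applies).
    top_n_list : top-N gene-set sizes for the mode-stability analysis.
    contribution_n : N for the cumulative |log2FC| contribution statistic.
    enhancement_margin : log2 units by which the combined-stress fold
        change must exceed both single-stress fold changes.
    subgroup_k : number of hierarchical subgroups for retained candidates.
    pseudocount : added to group mean normalized counts before the log2
        ratio, so zero-count groups have finite fold changes.
    dispersion_floor : lower bound on the per-gene dispersion estimate.
    assignment_method : "discrete" (significance-gated sign patterns) or
        "correlation" (best-matching template on the standardized log2FC
        vector).
    """

    alpha: float = 0.05
    top_n_list: tuple[int, ...] = (500, 1000, 2000)
    contribution_n: int = 1000
    enhancement_margin: float = 0.0
    subgroup_k: int = 3
    rng_seed: int = 0
    pseudocount: float = 0.5
    dispersion_floor: float = 1e-8
    assignment_method: str = "discrete"
    condition_aliases: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        self.top_n_list = tuple(int(n) for n in self.top_n_list)
        if any(n < 1 for n in self.top_n_list):
            raise ConfigError("all top-N values must be >= 1")
        if self.contribution_n < 1:
            raise ConfigError("contribution_n must be >= 1")
        if self.enhancement_margin < 0:
            raise ConfigError("enhancement_margin must be >= 0")
        if self.subgroup_k < 1:
            raise ConfigError("subgroup_k must be >= 1")
        if self.assignment_method not in ("discrete", "correlation"):
            raise ConfigError(f"unknown assignment_method {self.assignment_method!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts(path, design_path, aliases: Mapping[str, str] | None = None):
    """Read a counts TSV and its design TSV into validated objects.

    The counts file is rectangular, with a header row of sample ids and
    the first column holding gene ids.  The design file has two columns
    (sample_id, condition) with or without a header.  Samples present in
    the counts but absent from the design raise a :class:`ValidationError`;
    gene order is preserved from the file.
    """
    path, design_path = Path(path), Path(design_path)
    try:
        counts_df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"malformed counts file {path}: {exc}") from exc
    if counts_df.isna().to_numpy().any():
        row = counts_df.index[counts_df.isna().any(axis=1)][0]
        raise ParseError(f"malformed counts file {path}: missing value in row {row!r}")
    try:
        numeric = counts_df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric count in {path}: {exc}") from exc
    matrix = CountMatrix(numeric)

    try:
        design_df = pd.read_csv(design_path, sep="\t", header=None, comment="#", dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"malformed design file {design_path}: {exc}") from exc
    if design_df.shape[1] != 2:
        raise ParseError(
            f"design file {design_path} must have two columns, found {design_df.shape[1]}"
        )
    # tolerate an optional header row
    if str(design_df.iloc[0, 0]).lower() in ("sample", "sample_id") or str(
        design_df.iloc[0, 1]
    ).lower() in ("condition", "group"):
        design_df = design_df.iloc[1:]
    design = Design(dict(zip(design_df[0], design_df[1])), aliases=aliases)
    design.validate_against(matrix)
    return matrix, design


def read_annotations(path) -> AnnotationTable:
    """Read a gene annotation TSV with columns (gene_id, annotation[, effect])."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"malformed annotation file {path}: {exc}") from exc
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "gene_id" not in cols:
        df.columns = ["gene_id", "annotation", "effect"][: df.shape[1]]
    ann = dict(zip(df["gene_id"], df["annotation"])) if "annotation" in df.columns else {}
    eff = dict(zip(df["gene_id"], df["effect"])) if "effect" in df.columns else {}
    return AnnotationTable(ann, eff)


def write_table(records: pd.DataFrame, path) -> None:
    """Write a result table as TSV with header.

    Floats are formatted to :data:`FLOAT_DIGITS` significant digits so a
    round trip reproduces string/integer fields bit-exactly and floats to
    that precision.
    """
    if records is None:
        raise ValidationError("cannot write a null record set")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, float_format=f"%.{FLOAT_DIGITS}g")


def read_table(path) -> pd.DataFrame:
    """Read back a result TSV written by :func:`write_table`."""
    try:
        return pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"malformed table {path}: {exc}") from exc


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
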