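"""Dual-species probe-level expression handling.

In a xenograft, human transcripts report the tumor compartment and mouse
transcripts the stroma, so a single microarray hybridization yields two
species-resolved expression profiles.  This module loads probe-level
log2 matrices, applies the three probe-filtering rules used before
crosstalk inference — a per-probe significance prefilter (at least one
treated-vs-control contrast with p below threshold), removal of
cross-species-hybridizing probes via a blacklist, and collapse to one
probe per gene by largest mean intensity across all samples — and calls
genes "expressed" against a configurable intensity floor.

All three filters only select rows; no intensity value is ever modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "brafi", "anti_vegfa", "combo")
TREATED_CONDITIONS = ("brafi", "anti_vegfa", "combo")


@dataclass
class SampleSheet:
    """Sample → condition/replicate assignment for the four-arm design."""

    table: pd.DataFrame  # columns: sample_id, condition, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet lacks columns {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in sample sheet")
        bad = set(self.table["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions in sample sheet: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_of(self, condition: str) -> list[str]:
        return list(self.table.loc[self.table["condition"] == condition, "sample_id"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Log2 intensities (rows × samples) with per-row species/gene metadata.

    ``level`` is ``"probe"`` (row ids are probe ids) or ``"gene"`` (row ids
    are ``species:gene`` keys, which keeps same-named human/mouse genes
    distinct).
    """

    data: pd.DataFrame
    row_meta: pd.DataFrame  # columns: species, gene (index aligned with data)
    level: str = "probe"

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValueError(f"level must be 'probe' or 'gene', got {self.level!r}")
        if not self.data.index.equals(self.row_meta.index):
            raise ValueError("data and row_meta must share the same row index")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate row ids in expression matrix")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def subset(self, row_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = self.data.index.isin(set(row_ids))
        return replace(self, data=self.data.loc[keep], row_meta=self.row_meta.loc[keep])

    def to_tsv(self, path: str | Path) -> None:
        first = "probe_id" if self.level == "probe" else "row_id"
        self.data.rename_axis(first).to_csv(path, sep="\t")


def load_expression(
    matrix_path: str | Path,
    annotation_path: str | Path,
    samples_path: str | Path,
) -> tuple[ExpressionMatrix, SampleSheet]:
    """Load a probe-level TSV matrix and join it to its probe annotation.

    Probes absent from the annotation are dropped (count logged).  Columns
    are reordered to sample-sheet order; a matrix sample missing from the
    sheet is a fatal error naming the sample.
    """
    sheet = SampleSheet.from_tsv(samples_path)
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    missing = [s for s in raw.columns if s not in set(sheet.sample_ids)]
    if missing:
        raise ValueError(f"samples in matrix but not in sample sheet: {missing}")
    absent = [s for s in sheet.sample_ids if s not in raw.columns]
    if absent:
        raise ValueError(f"samples in sheet but not in matrix: {absent}")
    try:
        data = raw[sheet.sample_ids].astype(float)
    except ValueError as err:
        raise ValueError(f"non-numeric cell in expression matrix {matrix_path}: {err}") from err

    annot = read_annotation(annotation_path)
    keep = data.index.intersection(annot.index)
    n_drop = len(data) - len(keep)
    if n_drop:
        logger.warning("load_expression: dropped %d unannotated probes", n_drop)
    data = data.loc[keep]
    meta = annot.loc[keep, ["species", "gene"]]
    return ExpressionMatrix(data, meta, level="probe"), sheet


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Probe annotation TSV: probe_id, species, gene, optional cross_hyb (0/1)."""
    annot = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "species", "gene"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"annotation {path} lacks columns {sorted(missing)}")
    if annot["probe_id"].duplicated().any():
        raise ValueError("duplicate probe_ids in annotation")
    annot = annot.set_index("probe_id")
    if "cross_hyb" in annot.columns:
        annot["cross_hyb"] = annot["cross_hyb"].astype(int).astype(bool)
    else:
        annot["cross_hyb"] = False
    return annot


def read_blacklist(path: str | Path) -> set[str]:
    """Plain-text probe blacklist, one id per line, ``#`` comments allowed."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            out.add(entry)
    return out


def significance_prefilter(
    probe_pvalues: pd.DataFrame, alpha: float = 0.05
) -> tuple[set[str], pd.Series]:
    """Retain probes with at least one treated-vs-control contrast p < alpha.

    ``probe_pvalues`` is probes × treated conditions (raw p).  The
    inequality is strict, so a probe sitting exactly at the threshold in
    every contrast is dropped.  Returns the retained id set and the
    per-probe boolean retention flag.
    """
    vals = probe_pvalues.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any() or not np.isfinite(vals).all():
        raise ValueError("p-values must lie in [0, 1]")
    flags = pd.Series(vals.min(axis=1) < alpha, index=probe_pvalues.index)
    return set(probe_pvalues.index[flags]), flags


def remove_cross_hybridizing(matrix: ExpressionMatrix, blacklist: set[str]) -> ExpressionMatrix:
    """Drop blacklisted probes; all surviving rows are untouched."""
    if matrix.level != "probe":
        raise ValueError("cross-hybridization removal applies to probe-level matrices")
    n_unknown = len(blacklist - set(matrix.data.index))
    if n_unknown:
        logger.info("remove_cross_hybridizing: %d blacklist ids not in matrix", n_unknown)
    keep = [p for p in matrix.data.index if p not in blacklist]
    return matrix.subset(keep)


def collapse_to_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per (species, gene) keep the probe with the largest mean across all samples.

    Values are copied unchanged from the winning probe; ties are broken by
    the lexicographically smallest probe id.  Gene-level row ids are
    ``species:gene``.
    """
    if matrix.level != "probe":
        raise ValueError("collapse_to_genes expects a probe-level matrix")
    if matrix.n_rows == 0:
        empty = matrix.data.iloc[:0]
        return ExpressionMatrix(empty, matrix.row_meta.iloc[:0], level="gene")
    if matrix.row_meta["gene"].isna().any() or (matrix.row_meta["gene"] == "").any():
        raise ValueError("all probes must carry a gene annotation before collapse")
    ranking = matrix.row_meta.assign(
        _mean=matrix.data.mean(axis=1), _probe=matrix.data.index
    ).sort_values(["species", "gene", "_mean", "_probe"], ascending=[True, True, False, True])
    winners = ranking.drop_duplicates(["species", "gene"], keep="first")
    data = matrix.data.loc[winners["_probe"]]
    row_ids = winners["species"].str.cat(winners["gene"], sep=":")
    data = data.set_axis(row_ids, axis=0)
    meta = winners[["species", "gene"]].set_axis(row_ids, axis=0)
    return ExpressionMatrix(data, meta, level="gene")


def condition_means(matrix: ExpressionMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-row mean log2 intensity within each condition (rows × conditions)."""
    return pd.DataFrame(
        {c: matrix.data[sheet.samples_of(c)].mean(axis=1) for c in CONDITIONS}
    )


def expression_floor(matrix: ExpressionMatrix) -> pd.Series:
    """Default relative floor: per-species median of gene-level mean intensity."""
    means = matrix.data.mean(axis=1)
    return means.groupby(matrix.row_meta["species"]).median()


def expression_call(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    floor: float | str = "auto",
    scope: tuple[str, ...] = CONDITIONS,
) -> set[tuple[str, str]]:
    """Genes called expressed: condition mean ≥ floor in ≥ 1 in-scope condition.

    ``floor="auto"`` uses the per-species median of gene mean intensities —
    a platform-independent relative floor.  Returns ``(species, gene)``
    pairs.
    """
    if matrix.level != "gene":
        raise ValueError("expression_call expects a gene-level matrix")
    if not scope:
        raise ValueError("expression_call scope must name at least one condition")
    bad = set(scope) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions in scope: {sorted(bad)}")
    means = condition_means(matrix, sheet)[list(scope)]
    if floor == "auto":
        per_row_floor = matrix.row_meta["species"].map(expression_floor(matrix))
    else:
        per_row_floor = pd.Series(float(floor), index=matrix.data.index)
    called = (means.ge(per_row_floor, axis=0)).any(axis=1)
    meta = matrix.row_meta[called]
    return set(zip(meta["species"], meta["gene"]))
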