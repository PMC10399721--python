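"""Tumor–stroma ligand–receptor crosstalk inference.

Per-gene differential expression is a plain two-group t contrast on log2
intensities (pooled variance by default, Welch optional) yielding the
triple (log2ratio, raw p, BH-adjusted p) for each treated condition
against control, adjusted across all genes of one species within one
condition.  Tumor-expressed (human) ligands are intersected with
stroma-expressed (mouse) receptors through a directional compendium, and
ligands significant *only* under the dual-therapy (combo) arm are flagged
and ranked by combo log2ratio — the top of that ranking is the headline
tumor-derived signal.

This module is fully deterministic; randomness lives in
:mod:`xenotalk.simulate`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compendium import LRCompendium
from .expression import (
    CONDITIONS,
    TREATED_CONDITIONS,
    ExpressionMatrix,
    SampleSheet,
    collapse_to_genes,
    expression_call,
    remove_cross_hybridizing,
    significance_prefilter,
)

logger = logging.getLogger(__name__)

VarianceMode = Literal["pooled", "welch"]
PMode = Literal["raw", "bh"]


def two_group_contrast(
    treated: Sequence[float],
    control: Sequence[float],
    variance_mode: VarianceMode = "pooled",
) -> tuple[float, float]:
    """Two-sided t contrast on log2 values: (mean difference, raw p).

    Degenerate zero-variance groups follow the documented convention:
    p = 1 when the means are also equal, p = 0 otherwise.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("each group needs at least 2 values")
    log2ratio = float(t.mean() - c.mean())
    if t.var(ddof=1) == 0.0 and c.var(ddof=1) == 0.0:
        return log2ratio, 1.0 if log2ratio == 0.0 else 0.0
    res = stats.ttest_ind(t, c, equal_var=(variance_mode == "pooled"))
    return log2ratio, float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def condition_contrasts(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    conditions: Sequence[str] = TREATED_CONDITIONS,
    variance_mode: VarianceMode = "pooled",
) -> pd.DataFrame:
    """Per-row contrasts of each treated condition against control.

    Returns a long table (row_id, species, gene, condition, log2ratio,
    p_raw) with one row per matrix row × condition, computed vectorized.
    """
    control = matrix.data[sheet.samples_of("control")].to_numpy(dtype=float)
    if control.shape[1] < 2:
        raise ValueError("control arm needs at least 2 replicates")
    frames = []
    for cond in conditions:
        treated = matrix.data[sheet.samples_of(cond)].to_numpy(dtype=float)
        if treated.shape[1] < 2:
            raise ValueError(f"condition {cond!r} needs at least 2 replicates")
        log2ratio = treated.mean(axis=1) - control.mean(axis=1)
        res = stats.ttest_ind(
            treated, control, axis=1, equal_var=(variance_mode == "pooled")
        )
        p_raw = np.asarray(res.pvalue, dtype=float)
        # zero-variance convention, vectorized
        degenerate = (treated.var(axis=1, ddof=1) == 0) & (control.var(axis=1, ddof=1) == 0)
        p_raw[degenerate] = np.where(log2ratio[degenerate] == 0.0, 1.0, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "row_id": matrix.data.index,
                    "species": matrix.row_meta["species"].to_numpy(),
                    "gene": matrix.row_meta["gene"].to_numpy(),
                    "condition": cond,
                    "log2ratio": log2ratio,
                    "p_raw": p_raw,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def add_bh(contrasts: pd.DataFrame) -> pd.DataFrame:
    """Attach BH-adjusted p within each (species, condition) family."""
    out = contrasts.copy()
    out["p_bh"] = (
        out.groupby(["species", "condition"], group_keys=False)["p_raw"]
        .transform(lambda p: pd.Series(bh_adjust(p.to_numpy()), index=p.index))
    )
    return out


def probe_prefilter_pvalues(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    variance_mode: VarianceMode = "pooled",
) -> pd.DataFrame:
    """Per-probe raw p for each treated condition (probes × conditions)."""
    long = condition_contrasts(matrix, sheet, TREATED_CONDITIONS, variance_mode)
    return long.pivot(index="row_id", columns="condition", values="p_raw").loc[
        matrix.data.index
    ]


def condition_specific_ligands(
    results: pd.DataFrame,
    alpha: float = 0.05,
    p_mode: PMode = "raw",
    target: str = "combo",
    ligands: set[str] | None = None,
) -> set[str]:
    """Ligands significant in ``target`` and in no other treated condition.

    ``results`` is a long human-gene contrast table with columns gene,
    condition, p_raw, p_bh covering all three treated conditions.  A gene
    is included iff p < alpha in the target condition and p ≥ alpha in
    both others (p column chosen by ``p_mode``).  A considered ligand
    missing any condition is a fatal error naming it.
    """
    pcol = "p_raw" if p_mode == "raw" else "p_bh"
    table = results if ligands is None else results[results["gene"].isin(ligands)]
    wide = table.pivot_table(index="gene", columns="condition", values=pcol)
    wide = wide.reindex(columns=list(TREATED_CONDITIONS))
    incomplete = sorted(wide.index[wide.isna().any(axis=1)])
    if incomplete:
        raise ValueError(f"ligands missing a condition contrast: {incomplete}")
    if ligands is not None:
        absent = ligands - set(wide.index)
        if absent:
            raise ValueError(f"ligands missing a condition contrast: {sorted(absent)}")
    if not len(wide):
        return set()
    others = [c for c in TREATED_CONDITIONS if c != target]
    hit = (wide[target] < alpha) & (wide[others] >= alpha).all(axis=1)
    return set(wide.index[hit])


@dataclass
class CrosstalkCandidate:
    """Tumor-expressed ligand with ≥1 cognate stroma-expressed receptor."""

    ligand: str
    receptors: set[str]
    significant: dict[str, bool] = field(default_factory=dict)
    combo_log2ratio: float = float("nan")


def intersect_crosstalk(
    tumor_ligands: set[str],
    stroma_receptors: set[str],
    compendium: LRCompendium,
) -> list[CrosstalkCandidate]:
    """Intersect expressed tumor ligands with expressed stroma receptors.

    A candidate is emitted for each tumor-expressed ligand whose compendium
    receptors intersect the stroma-expressed set; its receptor field is
    that intersection.  Candidates come back sorted by ligand symbol.
    """
    out = []
    for ligand in sorted(tumor_ligands):
        shared = compendium.receptors_of(ligand) & stroma_receptors
        if shared:
            out.append(CrosstalkCandidate(ligand, shared))
    return out


def rank_by_upregulation(
    candidates: list[CrosstalkCandidate],
    combo_results: pd.DataFrame,
    restrict: set[str] | None = None,
) -> list[str]:
    """Order candidate ligands by descending combo log2ratio (ties: symbol).

    ``combo_results`` is the human combo-condition contrast table.  When
    ``restrict`` is given, only those ligands are ranked (e.g. the
    combo-specific set).  The first element is the headline ligand.
    """
    lr = combo_results.set_index("gene")["log2ratio"]
    pool = [c.ligand for c in candidates if restrict is None or c.ligand in restrict]
    missing = [l for l in pool if l not in lr.index]
    if missing:
        raise ValueError(f"candidates without a combo contrast: {missing}")
    return sorted(pool, key=lambda g: (-lr[g], g))


@dataclass
class CrosstalkParams:
    """Analysis knobs with paper-style defaults.

    ``prefilter_alpha=None`` disables the probe significance prefilter;
    ``floor`` is a log2 intensity or ``"auto"`` (per-species median).
    """

    alpha: float = 0.05
    p_mode: PMode = "raw"
    variance_mode: VarianceMode = "pooled"
    floor: float | str = "auto"
    prefilter_alpha: float | None = 0.05
    scope: tuple[str, ...] = CONDITIONS


@dataclass
class CrosstalkReport:
    """Pipeline output: candidates, counts, and the ranked combo-specific list."""

    candidates: list[CrosstalkCandidate]
    combo_specific: list[str]  # ordered by descending combo log2ratio
    contrasts: pd.DataFrame
    n_candidate_ligands: int
    n_receptors: int
    tumor_expressed: set[str]
    stroma_expressed: set[str]

    @property
    def top_ligand(self) -> str | None:
        return self.combo_specific[0] if self.combo_specific else None

    def candidate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand": [c.ligand for c in self.candidates],
                "receptors": [",".join(sorted(c.receptors)) for c in self.candidates],
                "combo_specific": [c.ligand in set(self.combo_specific) for c in self.candidates],
                "combo_log2ratio": [c.combo_log2ratio for c in self.candidates],
            }
        )

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        path = outdir / "crosstalk_report.tsv"
        self.candidate_frame().to_csv(path, sep="\t", index=False)
        written.append(path)
        path = outdir / "combo_specific_ligands.tsv"
        pd.DataFrame({"rank": range(1, len(self.combo_specific) + 1),
                      "ligand": self.combo_specific}).to_csv(path, sep="\t", index=False)
        written.append(path)
        for (species, cond), sub in self.contrasts.groupby(["species", "condition"]):
            path = outdir / f"contrasts_{species}_{cond}.tsv"
            sub[["gene", "log2ratio", "p_raw", "p_bh"]].to_csv(path, sep="\t", index=False)
            written.append(path)
        return written


def run_crosstalk(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    blacklist: set[str],
    compendium: LRCompendium,
    params: CrosstalkParams | None = None,
) -> CrosstalkReport:
    """Execute the full crosstalk pipeline on in-memory inputs.

    Stages: probe significance prefilter → cross-hybridizing blacklist →
    per-gene collapse → expression calls → gene contrasts with BH →
    compendium intersection → combo-only detection → ranking.
    """
    params = params or CrosstalkParams()
    if matrix.n_rows == 0:
        raise ValueError("crosstalk: empty expression input")

    stage = "significance_prefilter"
    try:
        work = matrix
        if params.prefilter_alpha is not None:
            pvals = probe_prefilter_pvalues(work, sheet, params.variance_mode)
            retained, _ = significance_prefilter(pvals, params.prefilter_alpha)
            work = work.subset(retained)

        stage = "remove_cross_hybridizing"
        work = remove_cross_hybridizing(work, blacklist)

        stage = "collapse_to_genes"
        genes = collapse_to_genes(work)
        if genes.n_rows == 0:
            raise ValueError("no genes survive probe filtering")

        stage = "expression_call"
        calls = expression_call(genes, sheet, params.floor, params.scope)
        tumor_expressed = {g for sp, g in calls if sp == "human"}
        stroma_expressed = {g for sp, g in calls if sp == "mouse"}

        stage = "condition_contrasts"
        contrasts = add_bh(
            condition_contrasts(genes, sheet, TREATED_CONDITIONS, params.variance_mode)
        )

        stage = "intersect_crosstalk"
        candidates = intersect_crosstalk(tumor_expressed, stroma_expressed, compendium)
        candidate_ligands = {c.ligand for c in candidates}

        stage = "condition_specific_ligands"
        human = contrasts[contrasts["species"] == "human"]
        combo_specific = condition_specific_ligands(
            human, params.alpha, params.p_mode, "combo", ligands=candidate_ligands
        )
        mono_significant: set[str] = set()
        for cond in ("brafi", "anti_vegfa"):
            pcol = "p_raw" if params.p_mode == "raw" else "p_bh"
            sub = human[human["condition"] == cond]
            mono_significant |= set(sub.loc[sub[pcol] < params.alpha, "gene"])
        assert not (combo_specific & mono_significant & candidate_ligands), (
            "combo-specific set must be disjoint from monotherapy-significant ligands"
        )

        stage = "rank_by_upregulation"
        combo_tbl = human[human["condition"] == "combo"]
        ranked = rank_by_upregulation(candidates, combo_tbl, restrict=combo_specific)
        lr = combo_tbl.set_index("gene")["log2ratio"]
        sig = {}
        pcol = "p_raw" if params.p_mode == "raw" else "p_bh"
        for cond in TREATED_CONDITIONS:
            sub = human[human["condition"] == cond]
            sig[cond] = set(sub.loc[sub[pcol] < params.alpha, "gene"])
        for cand in candidates:
            cand.combo_log2ratio = float(lr.get(cand.ligand, np.nan))
            cand.significant = {c: cand.ligand in sig[c] for c in TREATED_CONDITIONS}
    except Exception as err:
        raise type(err)(f"[stage {stage}] {err}") from err

    return CrosstalkReport(
        candidates=candidates,
        combo_specific=ranked,
        contrasts=contrasts,
        n_candidate_ligands=len(candidates),
        n_receptors=len(set().union(*[c.receptors for c in candidates]) if candidates else set()),
        tumor_expressed=tumor_expressed,
        stroma_expressed=stroma_expressed,
    )
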