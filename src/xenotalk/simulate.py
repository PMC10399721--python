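"""Synthetic study generator.

Produces every input the analysis consumes, from explicit stochastic
models and a seed, together with the ground truth needed for recovery
tests:

* a dual-species probe-level log2 matrix for the four-arm design
  (control / BRAFi / anti-VEGFA / combo, default 3 replicates each) with
  1–3 probes per gene, independent homoscedastic normal noise, a planted
  set of combo-only up-regulated human ligands, decoy ligands shifted in
  a monotherapy arm, and a cross-hybridizing probe subset that doubles as
  the blacklist;
* a matching directional ligand–receptor compendium in which every
  planted ligand is guaranteed a stroma-expressed receptor and filler
  pairs use low-intensity ligand symbols;
* caliper growth cohorts with planted CR/DR/SR/NR response classes
  (exponential growth before treatment, class-specific on-treatment
  dynamics, lognormal measurement noise) and a volume-threshold surrogate
  survival endpoint.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .compendium import LRCompendium, merge_sources
from .expression import (
    CONDITIONS,
    ExpressionMatrix,
    SampleSheet,
    collapse_to_genes,
    expression_call,
    remove_cross_hybridizing,
)
from .preclinical import GrowthCurve, GrowthMeasurement, SurvivalRecord


@dataclass
class SimConfig:
    """Scaled-down study geometry (defaults mirror the real design's shape).

    Expression block: four conditions × ``n_replicates`` (default 3, the
    replicate count of the xenograft arrays), ~1–3 probes per gene, five
    planted combo-specific ligands among a 60-pair compendium.  Growth
    block: treatment starts at ~250 mm³; arms carry a planted response
    class per mouse, defaulting to the published triple-therapy cohort
    composition (10 CR / 6 DR / 5 SR of 21) plus an untreated arm.
    """

    # expression
    n_genes_human: int = 200
    n_genes_mouse: int = 150
    probes_per_gene: tuple[int, int] = (1, 3)
    n_replicates: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    probe_offset_sd: float = 0.3
    noise_sd: float = 0.25
    n_planted: int = 5
    planted_effect: float = 5.0
    n_decoys: int = 3
    decoy_effect: float = 3.0
    cross_hyb_fraction: float = 0.10
    compendium_size: int = 60
    # growth / survival
    baseline_volume: float = 250.0
    growth_rate: float = 0.06
    cr_decay: float = 0.15
    dr_plateau: float = 0.35
    dr_decay: float = 0.15
    sr_decay: float = 0.15
    sr_switch_day: int = 18
    sr_regrowth: float = 0.09
    measurement_cv: float = 0.10
    measurement_interval: int = 3
    study_end: int = 60
    detection_limit: float = 10.0
    endpoint_volume: float = 1500.0
    arms: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "control": ("NR",) * 7,
            "triple": ("CR",) * 10 + ("DR",) * 6 + ("SR",) * 5,
        }
    )

    def validate(self) -> None:
        counts = (
            self.n_genes_human, self.n_genes_mouse, self.n_replicates,
            self.compendium_size, self.measurement_interval, self.study_end,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not 0 <= self.cross_hyb_fraction <= 1:
            raise ValueError("cross_hyb_fraction must lie in [0, 1]")
        if not 0 < self.dr_plateau < 1:
            raise ValueError("dr_plateau must lie in (0, 1)")
        if self.n_planted + self.n_decoys > self.n_genes_human:
            raise ValueError("more planted+decoy ligands than human genes")
        if self.n_planted > self.n_genes_mouse:
            raise ValueError("more planted receptors than mouse genes")
        if self.compendium_size < self.n_planted + self.n_decoys:
            raise ValueError("compendium too small to host planted pairs")
        if not all(np.isfinite([self.planted_effect, self.decoy_effect])):
            raise ValueError("effect sizes must be finite")
        for arm, classes in self.arms.items():
            bad = set(classes) - {"CR", "DR", "SR", "NR"}
            if bad:
                raise ValueError(f"arm {arm!r} has unknown classes {sorted(bad)}")


@dataclass
class SimTruth:
    """Ground truth recorded by the generators for recovery tests."""

    planted_ligands: set[str] = field(default_factory=set)
    decoy_ligands: set[str] = field(default_factory=set)
    decoy_arms: dict[str, str] = field(default_factory=dict)
    planted_receptor_map: dict[str, str] = field(default_factory=dict)
    blacklist: set[str] = field(default_factory=set)
    tumor_expressed: set[str] = field(default_factory=set)
    stroma_expressed: set[str] = field(default_factory=set)
    low_expression_ligands: tuple[str, ...] = ()
    response_classes: dict[str, str] = field(default_factory=dict)
    progression_day: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.planted_ligands & self.decoy_ligands:
            raise ValueError("planted and decoy ligand sets must be disjoint")


def _gene_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def simulate_xeno_expression(
    config: SimConfig, seed: int = 0
) -> tuple[ExpressionMatrix, pd.DataFrame, SampleSheet, set[str], SimTruth]:
    """Generate the probe matrix, annotation, sample sheet, blacklist and truth.

    Model per probe and sample: gene baseline + probe offset + condition
    effect + N(0, noise_sd).  Planted ligands receive the effect in the
    combo arm only; each decoy in one monotherapy arm (alternating).
    Planted ligands, decoys and planted receptors get boosted baselines so
    they pass the expression call even without any treatment effect, and
    their probes are never flagged cross-hybridizing (the blacklist is a
    nuisance filter, not part of the signal).
    """
    config.validate()
    rng = np.random.default_rng(seed)

    human = _gene_names("HGN", config.n_genes_human)
    mouse = _gene_names("MGN", config.n_genes_mouse)
    picked = [str(g) for g in rng.choice(human, size=config.n_planted + config.n_decoys, replace=False)]
    planted = picked[: config.n_planted]
    decoys = picked[config.n_planted :]
    receptors = [str(g) for g in rng.choice(mouse, size=config.n_planted, replace=False)]
    decoy_arms = {d: ("brafi" if i % 2 == 0 else "anti_vegfa") for i, d in enumerate(decoys)}
    boosted = set(planted) | set(decoys) | set(receptors)

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": [f"{c}_{r + 1}" for c in CONDITIONS for r in range(config.n_replicates)],
                "condition": [c for c in CONDITIONS for _ in range(config.n_replicates)],
                "replicate": [r + 1 for _ in CONDITIONS for r in range(config.n_replicates)],
            }
        )
    )

    rows, species_col, gene_col = [], [], []
    lo, hi = config.probes_per_gene
    for sp, genes in (("human", human), ("mouse", mouse)):
        for g in genes:
            n_probes = int(rng.integers(lo, hi + 1))
            base = rng.normal(config.baseline_mean, config.baseline_sd)
            if g in boosted:
                base = config.baseline_mean + 2.0 + rng.normal(0.0, 0.5)
            for p in range(n_probes):
                rows.append((f"{g}_p{p + 1}", base + rng.normal(0.0, config.probe_offset_sd)))
                species_col.append(sp)
                gene_col.append(g)

    probe_ids = [r[0] for r in rows]
    baselines = np.array([r[1] for r in rows])
    n_probes_total = len(probe_ids)
    n_samples = len(sheet.sample_ids)
    values = baselines[:, None] + rng.normal(0.0, config.noise_sd, (n_probes_total, n_samples))

    gene_arr = np.array(gene_col)
    cond_arr = np.array([sheet.table["condition"].iloc[j] for j in range(n_samples)])
    for g in planted:
        values[np.ix_(gene_arr == g, cond_arr == "combo")] += config.planted_effect
    for d, arm in decoy_arms.items():
        values[np.ix_(gene_arr == d, cond_arr == arm)] += config.decoy_effect

    data = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                        columns=sheet.sample_ids)
    meta = pd.DataFrame({"species": species_col, "gene": gene_col}, index=data.index)
    matrix = ExpressionMatrix(data, meta, level="probe")

    eligible = [p for p, g in zip(probe_ids, gene_col) if g not in boosted]
    n_black = int(round(config.cross_hyb_fraction * n_probes_total))
    n_black = min(n_black, len(eligible))
    blacklist = (
        {str(p) for p in rng.choice(eligible, size=n_black, replace=False)} if n_black else set()
    )

    annotation = meta.reset_index().assign(
        cross_hyb=[int(p in blacklist) for p in probe_ids]
    )

    # expression truth, computed with the pipeline's own collapse + call rules
    clean_genes = collapse_to_genes(remove_cross_hybridizing(matrix, blacklist))
    calls = expression_call(clean_genes, sheet, floor="auto")
    tumor_expressed = {g for sp, g in calls if sp == "human"}
    stroma_expressed = {g for sp, g in calls if sp == "mouse"}
    human_means = clean_genes.data.mean(axis=1)[
        clean_genes.row_meta["species"] == "human"
    ]
    cutoff = human_means.quantile(0.40)
    low = tuple(
        sorted(
            g
            for g, m in zip(
                clean_genes.row_meta.loc[human_means.index, "gene"], human_means
            )
            if m < cutoff and g not in boosted
        )
    )

    truth = SimTruth(
        planted_ligands=set(planted),
        decoy_ligands=set(decoys),
        decoy_arms=decoy_arms,
        planted_receptor_map=dict(zip(planted, receptors)),
        blacklist=blacklist,
        tumor_expressed=tumor_expressed,
        stroma_expressed=stroma_expressed,
        low_expression_ligands=low,
    )
    return matrix, annotation, sheet, blacklist, truth


def simulate_compendium(config: SimConfig, truth: SimTruth, seed: int = 0) -> LRCompendium:
    """Build a compendium hosting the planted pairs plus low-intensity filler.

    Every planted ligand gets its designated stroma-expressed receptor and
    every decoy a random stroma-expressed receptor (so decoys are real
    candidates whose exclusion is exercised).  Filler ligands are drawn
    from symbols well below the expression floor, so filler pairs never
    produce crosstalk candidates.  Pairs are split across two source
    tables with a small overlap to exercise the merge path.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if not truth.stroma_expressed:
        raise ValueError("truth has no stroma-expressed receptors to plant against")

    pairs: list[tuple[str, str]] = []
    for ligand, receptor in sorted(truth.planted_receptor_map.items()):
        if receptor not in truth.stroma_expressed:
            raise ValueError(f"planted receptor {receptor} is not stroma-expressed")
        pairs.append((ligand, receptor))
    stroma_pool = sorted(truth.stroma_expressed)
    for decoy in sorted(truth.decoy_ligands):
        pairs.append((decoy, stroma_pool[int(rng.integers(len(stroma_pool)))]))

    filler_ligands = list(truth.low_expression_ligands)
    mouse_pool = _gene_names("MGN", config.n_genes_mouse)
    if not filler_ligands and config.compendium_size > len(pairs):
        raise ValueError("no low-expression ligand symbols available for filler pairs")
    seen = set(pairs)
    guard = 0
    while len(pairs) < config.compendium_size:
        pair = (
            filler_ligands[int(rng.integers(len(filler_ligands)))],
            mouse_pool[int(rng.integers(len(mouse_pool)))],
        )
        guard += 1
        if guard > 100 * config.compendium_size:
            raise ValueError("cannot fill compendium without duplicate pairs")
        if pair in seen:
            continue
        seen.add(pair)
        pairs.append(pair)

    table_a, table_b = [], []
    for i, (ligand, receptor) in enumerate(pairs):
        row = {"ligand": ligand, "receptor": receptor}
        in_both = rng.random() < 0.1
        if i % 2 == 0 or in_both:
            table_a.append({**row, "source": "iuphar"})
        if i % 2 == 1 or in_both:
            table_b.append({**row, "source": "dlrp"})
    comp = merge_sources([pd.DataFrame(table_a), pd.DataFrame(table_b)])
    assert len(comp) == len(pairs)
    return comp


def _true_volume(config: SimConfig, cls: str, t: float) -> float:
    v0 = config.baseline_volume
    if cls == "NR":
        return v0 * np.exp(config.growth_rate * t)
    if cls == "CR":
        return v0 * np.exp(-config.cr_decay * t)
    if cls == "DR":
        return v0 * (config.dr_plateau + (1 - config.dr_plateau) * np.exp(-config.dr_decay * t))
    if cls == "SR":
        if t < config.sr_switch_day:
            return v0 * np.exp(-config.sr_decay * t)
        nadir = v0 * np.exp(-config.sr_decay * config.sr_switch_day)
        return nadir * np.exp(config.sr_regrowth * (t - config.sr_switch_day))
    raise ValueError(f"unknown response class {cls!r}")


def simulate_growth_cohort(
    config: SimConfig, seed: int = 0
) -> tuple[list[GrowthCurve], list[SurvivalRecord], SimTruth]:
    """Generate caliper growth curves and surrogate survival records.

    Treatment starts at day 0 at the ~250 mm³ enrollment volume.  The
    measured volume is the true class trajectory times lognormal noise
    (sd ``measurement_cv`` on the log scale); volumes under the caliper
    detection limit are recorded as 0 (no palpable tumor).  Caliper length
    and width are back-computed with the fixed aspect width = length/2, so
    length·width²/2 returns the simulated volume exactly.  The survival
    event is a volume surrogate: the first day the recorded volume reaches
    ``endpoint_volume``; mice never reaching it are censored at study end.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    days = list(range(0, config.study_end + 1, config.measurement_interval))
    curves, survival = [], []
    truth = SimTruth()
    for arm, classes in config.arms.items():
        for i, cls in enumerate(classes):
            mouse = f"{arm}_{i + 1:02d}"
            baseline_noise = np.exp(rng.normal(0.0, config.measurement_cv))
            measurements = []
            event_day: float | None = None
            progression: float | None = None
            for day in days:
                vol = _true_volume(config, cls, day)
                if day > 0 and progression is None and vol > config.baseline_volume:
                    progression = float(day)
                measured = vol * (
                    baseline_noise if day == 0 else np.exp(rng.normal(0.0, config.measurement_cv))
                )
                if measured < config.detection_limit:
                    measured = 0.0
                if event_day is None and measured >= config.endpoint_volume and day > 0:
                    event_day = float(day)
                length = 2.0 * measured ** (1.0 / 3.0)
                measurements.append(GrowthMeasurement(mouse, day, length, length / 2.0))
            curves.append(GrowthCurve(mouse, arm, measurements, treatment_start=0))
            if event_day is not None:
                survival.append(SurvivalRecord(mouse, event_day, 1, arm))
            else:
                survival.append(SurvivalRecord(mouse, float(config.study_end), 0, arm))
            truth.response_classes[mouse] = cls
            if progression is not None:
                truth.progression_day[mouse] = progression
    return curves, survival, truth


# ---------------------------------------------------------------------------
# bundle writers (the exact TSV/CSV dialects the analysis modules read)


def write_expression_bundle(
    outdir: str | Path,
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    sheet: SampleSheet,
    blacklist: set[str],
    compendium: LRCompendium,
    truth: SimTruth,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "samples": outdir / "samples.tsv",
        "blacklist": outdir / "blacklist.txt",
        "compendium": outdir / "compendium.tsv",
        "truth": outdir / "truth.tsv",
    }
    matrix.to_tsv(paths["expression"])
    annotation.to_csv(paths["annotation"], sep="\t", index=False)
    sheet.to_tsv(paths["samples"])
    paths["blacklist"].write_text("\n".join(sorted(blacklist)) + "\n")
    compendium.to_tsv(paths["compendium"])
    rows = (
        [("planted_ligand", g, truth.planted_receptor_map.get(g, "")) for g in sorted(truth.planted_ligands)]
        + [("decoy_ligand", g, truth.decoy_arms.get(g, "")) for g in sorted(truth.decoy_ligands)]
        + [("stroma_receptor", g, "") for g in sorted(truth.stroma_expressed)]
    )
    pd.DataFrame(rows, columns=["kind", "gene", "detail"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths


def write_growth_bundle(
    outdir: str | Path,
    curves: Sequence[GrowthCurve],
    survival: Sequence[SurvivalRecord],
    truth: SimTruth,
) -> dict[str, Path]:
    from .preclinical import write_growth_log, write_survival

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "growth": outdir / "growth.csv",
        "survival": outdir / "survival.csv",
        "truth": outdir / "truth_responses.tsv",
    }
    write_growth_log(curves, paths["growth"])
    write_survival(survival, paths["survival"])
    pd.DataFrame(
        {
            "mouse_id": sorted(truth.response_classes),
            "response": [truth.response_classes[m] for m in sorted(truth.response_classes)],
            "progression_day": [
                truth.progression_day.get(m, "") for m in sorted(truth.response_classes)
            ],
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
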