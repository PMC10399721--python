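"""Directional ligand–receptor interaction compendium.

A compendium is a deduplicated, ordered collection of directional
ligand → receptor gene pairs assembled from one or more curated source
tables (e.g. IUPHAR, DLRP exports).  Gene symbols are harmonized across
species before deduplication so that a human ligand row can be joined
with a mouse receptor row: human and mouse orthologs conventionally
differ only by case (CSF2 vs Csf2), so the default harmonization rule is
upper-casing, with an explicit override table for non-trivial pairs.

Directionality is preserved: (A, B) and (B, A) are distinct interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("human", "mouse")


@dataclass(frozen=True)
class LRInteraction:
    """One directional ligand → receptor pair with source provenance."""

    ligand: str
    receptor: str
    sources: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor symbols must be non-empty")
        if not self.sources:
            raise ValueError("an interaction needs at least one source tag")


@dataclass
class SymbolMap:
    """Total mapping raw gene symbol → canonical symbol.

    Explicit entries (keyed by ``(raw, species)``) win; everything else
    falls back to upper-casing.  The mapping is idempotent: canonical
    symbols map to themselves.
    """

    explicit: dict[tuple[str, str], str] = field(default_factory=dict)

    def normalize(self, raw: str, species: str) -> str:
        if not raw:
            raise ValueError("cannot normalize an empty gene symbol")
        if species not in SPECIES:
            raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
        return self.explicit.get((raw, species), raw.upper())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SymbolMap":
        """Read an override table with columns ``raw``, ``species``, ``canonical``."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"raw", "species", "canonical"} - set(df.columns)
        if missing:
            raise ValueError(f"symbol map {path} lacks columns {sorted(missing)}")
        return cls({(r.raw, r.species): r.canonical for r in df.itertuples()})


def normalize_symbol(raw: str, species: str, symbol_map: SymbolMap | None = None) -> str:
    """Canonicalize a gene symbol (explicit map entry wins, else uppercase)."""
    return (symbol_map or SymbolMap()).normalize(raw, species)


class LRCompendium:
    """Ordered, deduplicated set of directional ligand–receptor interactions."""

    def __init__(self, interactions: Iterable[LRInteraction] = ()) -> None:
        self.interactions: list[LRInteraction] = []
        self._by_pair: dict[tuple[str, str], int] = {}
        self.ligand_index: dict[str, set[str]] = {}
        self.receptor_index: dict[str, set[str]] = {}
        for inter in interactions:
            self._add(inter)

    def _add(self, inter: LRInteraction) -> None:
        key = (inter.ligand, inter.receptor)
        if key in self._by_pair:
            idx = self._by_pair[key]
            old = self.interactions[idx]
            self.interactions[idx] = LRInteraction(
                old.ligand, old.receptor, old.sources | inter.sources
            )
        else:
            self._by_pair[key] = len(self.interactions)
            self.interactions.append(inter)
            self.ligand_index.setdefault(inter.ligand, set()).add(inter.receptor)
            self.receptor_index.setdefault(inter.receptor, set()).add(inter.ligand)

    def __len__(self) -> int:
        return len(self.interactions)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._by_pair

    @property
    def ligands(self) -> set[str]:
        return set(self.ligand_index)

    @property
    def receptors(self) -> set[str]:
        return set(self.receptor_index)

    def receptors_of(self, ligand: str) -> set[str]:
        """Cognate receptors of ``ligand``; empty set if the ligand is unknown."""
        return set(self.ligand_index.get(ligand, set()))

    def ligands_of(self, receptor: str) -> set[str]:
        return set(self.receptor_index.get(receptor, set()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand": [i.ligand for i in self.interactions],
                "receptor": [i.receptor for i in self.interactions],
                "source": [",".join(sorted(i.sources)) for i in self.interactions],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, symbol_map: SymbolMap | None = None) -> "LRCompendium":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return merge_sources([df], symbol_map)


def load_toy_compendium() -> LRCompendium:
    """Small packaged fixture compendium for examples and tests.

    Canonical upper-case symbols; the GM-CSF receptor alpha chain is listed
    under its canonical symbol CSF2RA (the mouse gene is Csf2ra; the
    occasionally seen spelling "Csfr2a" is a transposition).
    """
    import io
    from importlib import resources

    text = resources.files("xenotalk").joinpath("data/toy_compendium.tsv").read_text()
    return merge_sources([pd.read_csv(io.StringIO(text), sep="\t", dtype=str)])


def merge_sources(
    tables: Iterable[pd.DataFrame | Mapping],
    symbol_map: SymbolMap | None = None,
    ligand_species: str = "human",
    receptor_species: str = "mouse",
) -> LRCompendium:
    """Merge raw interaction tables into one deduplicated compendium.

    Each table needs columns ``ligand``, ``receptor``, ``source``.  Symbols
    are normalized (ligands with the ligand-side species convention,
    receptors with the receptor-side one), duplicate pairs are collapsed
    with the union of their source tags, and interaction order is order of
    first occurrence.  Rows with a missing ligand or receptor are rejected
    with a logged warning.
    """
    smap = symbol_map or SymbolMap()
    comp = LRCompendium()
    n_rejected = 0
    for table in tables:
        df = pd.DataFrame(table)
        missing = {"ligand", "receptor", "source"} - set(df.columns)
        if missing:
            raise ValueError(f"interaction table lacks columns {sorted(missing)}")
        for row in df.itertuples():
            lig, rec, src = row.ligand, row.receptor, row.source
            if not isinstance(lig, str) or not isinstance(rec, str) or not lig or not rec:
                n_rejected += 1
                continue
            comp._add(
                LRInteraction(
                    smap.normalize(lig, ligand_species),
                    smap.normalize(rec, receptor_species),
                    frozenset(src.split(",")) if isinstance(src, str) and src else frozenset(["unknown"]),
                )
            )
    if n_rejected:
        logger.warning("merge_sources: rejected %d rows with missing symbols", n_rejected)
    return comp
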