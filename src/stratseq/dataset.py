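"""Stratigraphic occurrence data: domain model, I/O, validation and screening.

A :class:`StratDataset` holds measured sections (ordered fossil-bearing levels
with taxon occurrences) and the taxa observed in them.  Each taxon observed in
a section defines two local biostratigraphic datums: a first appearance datum
(FAD) at its lowest occupied level and a last appearance datum (LAD) at its
highest.  Heights increase upward, i.e. toward younger strata; level indices
are 1-based and follow height order.

The module also provides the standard pre-optimization screens: dropping
thinly sampled sections, checking that all sections are connected through
shared taxa (a prerequisite for correlation), ranking sections by shared
faunal content, and the independent-bioevent resolution metric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("stratseq")

GROUPS = ("PF", "LBF", "SBF", "other")

FAD = "FAD"
LAD = "LAD"


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass(frozen=True)
class Taxon:
    """A taxonomic unit; ``group`` is an ecological category (PF/LBF/SBF)."""

    taxon_id: str
    name: str = ""
    genus: str = ""
    group: str = "other"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"taxon {self.taxon_id!r}: unknown group {self.group!r}; "
                f"expected one of {GROUPS}"
            )


@dataclass(frozen=True)
class BioEvent:
    """A first (FAD) or last (LAD) appearance datum of one taxon."""

    taxon_id: str
    kind: str  # FAD or LAD

    def __post_init__(self) -> None:
        if self.kind not in (FAD, LAD):
            raise ValidationError(f"event kind must be FAD or LAD, got {self.kind!r}")


@dataclass
class Section:
    """One measured section: strictly ascending heights plus occurrences.

    ``occurrences`` is a set of ``(taxon_id, level_index)`` with 1-based level
    indices.  ``weight`` scales this section's contribution to the composite
    misfit; the virtual marker section uses a large weight.
    """

    section_id: str
    heights: np.ndarray  # shape (n_levels,), strictly increasing upward
    occurrences: set[tuple[str, int]]
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 1 or self.heights.size == 0:
            raise ValidationError(f"section {self.section_id!r}: needs >=1 level")
        if not np.all(np.diff(self.heights) > 0):
            raise ValidationError(
                f"section {self.section_id!r}: heights must be strictly "
                "increasing with level_index (younger upward)"
            )
        if self.weight <= 0:
            raise ValidationError(f"section {self.section_id!r}: weight must be > 0")
        n = self.heights.size
        for taxon_id, lvl in self.occurrences:
            if not (1 <= lvl <= n):
                raise ValidationError(
                    f"section {self.section_id!r}: occurrence of {taxon_id!r} at "
                    f"level {lvl} outside 1..{n}"
                )

    @property
    def n_levels(self) -> int:
        return int(self.heights.size)

    @property
    def taxa(self) -> set[str]:
        return {t for t, _ in self.occurrences}

    def local_range(self, taxon_id: str) -> tuple[int, int]:
        """(lowest, highest) occupied level of ``taxon_id`` in this section."""
        lvls = [l for t, l in self.occurrences if t == taxon_id]
        if not lvls:
            raise KeyError(f"{taxon_id!r} not observed in section {self.section_id!r}")
        return min(lvls), max(lvls)

    def local_ranges(self) -> dict[str, tuple[int, int]]:
        out: dict[str, list[int]] = {}
        for t, l in self.occurrences:
            out.setdefault(t, []).append(l)
        return {t: (min(v), max(v)) for t, v in out.items()}

    def height_of(self, level_index: int) -> float:
        return float(self.heights[level_index - 1])


@dataclass
class StratDataset:
    """Taxa plus sections, with derived local FAD/LAD ranges."""

    taxa: dict[str, Taxon]
    sections: list[Section] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.section_id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate section_id in dataset")
        observed = set()
        for s in self.sections:
            unknown = s.taxa - self.taxa.keys()
            if unknown:
                raise ValidationError(
                    f"section {s.section_id!r} references unknown taxa {sorted(unknown)}"
                )
            observed |= s.taxa
        orphans = self.taxa.keys() - observed
        if orphans:
            raise ValidationError(
                f"taxa with zero occurrences: {sorted(orphans)}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_events(self) -> int:
        return 2 * len(self.taxa)

    def events(self) -> list[BioEvent]:
        out = []
        for tid in sorted(self.taxa):
            out.append(BioEvent(tid, FAD))
            out.append(BioEvent(tid, LAD))
        return out

    def section(self, section_id: str) -> Section:
        for s in self.sections:
            if s.section_id == section_id:
                return s
        raise KeyError(section_id)

    def summary(self) -> dict:
        comps = connectivity(self)
        return {
            "n_taxa": self.n_taxa,
            "n_events": self.n_events,
            "n_sections": len(self.sections),
            "n_occurrences": sum(len(s.occurrences) for s in self.sections),
            "n_components": len(comps),
            "correlatable": len(comps) == 1,
            "ranking": [[sid, sc] for sid, sc in rank_sections(self)],
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

SECTION_COLUMNS = ["section_id", "level_index", "height", "taxon", "genus", "group"]


def read_sections(path) -> StratDataset:
    """Read a section table (CSV, one row per occurrence) into a dataset.

    Required columns: ``section_id, level_index, height, taxon``; optional
    ``genus, group, weight``.  Duplicate (taxon, level) rows within a section
    collapse silently (logged).  Heights must be strictly increasing with
    level index inside every section.
    """
    try:
        df = pd.read_csv(path, dtype={"section_id": str, "taxon": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse section file {path}: {exc}") from exc
    missing = {"section_id", "level_index", "height", "taxon"} - set(df.columns)
    if missing:
        raise ValidationError(f"section file missing columns: {sorted(missing)}")
    bad = df["level_index"].isna() | df["height"].isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header + 1-based
        raise ValidationError(f"malformed row at line {line} of {path}")
    return dataset_from_frame(df)


def dataset_from_frame(df: pd.DataFrame) -> StratDataset:
    """Build a validated :class:`StratDataset` from an occurrence table.

    Rows with an empty taxon define a level without recording an occurrence
    (needed so sparsely occupied sections survive write/read round-trips).
    """
    df = df.copy()
    occ_rows_mask = df["taxon"].notna() & (df["taxon"].astype(str) != "")
    taxa: dict[str, Taxon] = {}
    for _, row in df[occ_rows_mask].drop_duplicates("taxon").iterrows():
        genus = str(row["genus"]) if "genus" in df.columns and pd.notna(row.get("genus")) else ""
        group = str(row["group"]) if "group" in df.columns and pd.notna(row.get("group")) else "other"
        taxa[str(row["taxon"])] = Taxon(str(row["taxon"]), name=str(row["taxon"]),
                                        genus=genus, group=group)
    sections = []
    for sid, sub in df.groupby("section_id", sort=True):
        levels = sub[["level_index", "height"]].drop_duplicates().sort_values("level_index")
        idx = levels["level_index"].to_numpy(dtype=int)
        if not np.array_equal(idx, np.arange(1, idx.size + 1)):
            raise ValidationError(
                f"section {sid!r}: level_index must be contiguous 1..n, got {idx.tolist()}"
            )
        hts = levels["height"].to_numpy(dtype=float)
        if not np.all(np.diff(hts) > 0):
            raise ValidationError(
                f"section {sid!r}: heights not strictly increasing with level_index"
            )
        occ_sub = sub[sub["taxon"].notna() & (sub["taxon"].astype(str) != "")]
        occ_rows = list(zip(occ_sub["taxon"].astype(str),
                            occ_sub["level_index"].astype(int)))
        occ = set(occ_rows)
        if len(occ) < len(occ_rows):
            logger.warning("section %s: %d duplicate occurrence rows collapsed",
                           sid, len(occ_rows) - len(occ))
        weight = float(sub["weight"].iloc[0]) if "weight" in df.columns and pd.notna(sub["weight"].iloc[0]) else 1.0
        sections.append(Section(str(sid), hts, occ, weight=weight))
    return StratDataset(taxa=taxa, sections=sections)


def write_sections(ds: StratDataset, path) -> None:
    """Write the dataset back to the occurrence-table dialect (round-trip safe)."""
    rows = []
    for s in ds.sections:
        occupied = {lvl for _, lvl in s.occurrences}
        for lvl in range(1, s.n_levels + 1):
            if lvl not in occupied:  # level-definition row, no occurrence
                rows.append({
                    "section_id": s.section_id, "level_index": lvl,
                    "height": s.height_of(lvl), "taxon": "",
                    "genus": "", "group": "", "weight": s.weight,
                })
        for taxon_id, lvl in sorted(s.occurrences):
            t = ds.taxa[taxon_id]
            rows.append({
                "section_id": s.section_id,
                "level_index": lvl,
                "height": s.height_of(lvl),
                "taxon": taxon_id,
                "genus": t.genus,
                "group": t.group,
                "weight": s.weight,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_summary(ds: StratDataset, path) -> None:
    with open(path, "w") as fh:
        json.dump(ds.summary(), fh, indent=2)


# ---------------------------------------------------------------------------
# Screening and ranking
# ---------------------------------------------------------------------------

def filter_sections(ds: StratDataset, min_events: int = 30) -> StratDataset:
    """Retain sections with strictly more than ``min_events`` local datums.

    Each locally observed taxon contributes two datums (its local FAD and
    LAD).  Taxa left without any hosting section are dropped.
    """
    if min_events < 0:
        raise ValueError("min_events must be >= 0")
    kept = [s for s in ds.sections if 2 * len(s.taxa) > min_events]
    if not kept:
        raise ValidationError(
            f"no section has more than {min_events} biostratigraphic events"
        )
    observed = set().union(*(s.taxa for s in kept))
    taxa = {tid: t for tid, t in ds.taxa.items() if tid in observed}
    dropped = ds.taxa.keys() - observed
    if dropped:
        logger.info("filter_sections: dropped %d taxa with no remaining section",
                    len(dropped))
    return StratDataset(taxa=taxa, sections=[replace(s) for s in kept])


def connectivity(ds: StratDataset) -> list[set[str]]:
    """Connected components of the section graph (edge = >=1 shared taxon).

    The dataset is globally correlatable iff there is a single component.
    """
    g = nx.Graph()
    g.add_nodes_from(s.section_id for s in ds.sections)
    by_taxon: dict[str, list[str]] = {}
    for s in ds.sections:
        for t in s.taxa:
            by_taxon.setdefault(t, []).append(s.section_id)
    for sids in by_taxon.values():
        for a, b in zip(sids, sids[1:]):
            g.add_edge(a, b)
    return [set(c) for c in nx.connected_components(g)]


def rank_sections(ds: StratDataset) -> list[tuple[str, float]]:
    """Rank sections by shared faunal content, best first.

    A section's score sums, over its taxa that also occur in at least one
    other section, that taxon's total occurrence count across the whole
    dataset.  Ties break lexically on section_id for determinism.
    """
    if not ds.sections:
        raise ValidationError("cannot rank an empty dataset")
    total_occ: dict[str, int] = {}
    n_sections_of: dict[str, int] = {}
    for s in ds.sections:
        for t in s.taxa:
            n_sections_of[t] = n_sections_of.get(t, 0) + 1
        for t, _ in s.occurrences:
            total_occ[t] = total_occ.get(t, 0) + 1
    scores = []
    for s in ds.sections:
        sc = sum(total_occ[t] for t in s.taxa if n_sections_of[t] > 1)
        scores.append((s.section_id, float(sc)))
    return sorted(scores, key=lambda p: (-p[1], p[0]))


def independent_event_resolution(ds: StratDataset) -> float:
    """Mean count per section of FAD/LAD datums at single-taxon levels.

    A datum is independent when no other taxon occurs at its stratigraphic
    level; more independent datums mean finer resolvable ordering.
    """
    if not ds.sections:
        raise ValidationError("empty dataset")
    counts = []
    for s in ds.sections:
        taxa_at_level: dict[int, set[str]] = {}
        for t, l in s.occurrences:
            taxa_at_level.setdefault(l, set()).add(t)
        n = 0
        for t, (lo, hi) in s.local_ranges().items():
            if taxa_at_level[lo] == {t}:  # local FAD
                n += 1
            if taxa_at_level[hi] == {t}:  # local LAD (same level for singletons)
                n += 1
        counts.append(n)
    return float(np.mean(counts))
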