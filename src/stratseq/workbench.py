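"""End-to-end pipeline: validate -> rank -> optimize -> calibrate -> diversity
-> correlate, with a reproducible JSON manifest.

The pipeline mirrors the standard four-step composite-correlation workflow:
(1) connectivity screening of the section network; (2) construction of a
highly weighted virtual section from the marker datums so that well-dated
index events anchor the composite; (3) evolutionary optimisation, optionally
seeded from prior composites or merged seed-parallel restarts; (4) level
clustering and smoothing-spline age calibration with a marker bootstrap.
Diversity and proxy-correlation stages then run on the calibrated composite.
Identical inputs and configuration produce identical outputs; every output
carries the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import associate, calibrate, dataset, diversity, evolve, penalty
from .associate import ProxySeries
from .calibrate import MarkerSet
from .dataset import FAD, LAD, Section, StratDataset, Taxon
from .evolve import EAConfig

logger = logging.getLogger("stratseq")


@dataclass
class RunConfig:
    sections_path: str = ""
    markers_path: str | None = None
    proxy_paths: list[str] = field(default_factory=list)
    out_dir: str = "stratseq_out"
    ea: EAConfig = field(default_factory=EAConfig)
    min_events: int = 0
    marker_weight: float = 10.0
    bin_width_myr: float = 0.2
    n_boot_age: int = 1000
    n_boot_rho: int = 10000
    rarefy_sizes: list[int] = field(default_factory=list)
    restarts: int = 1
    seed: int = 0
    group: str | None = None
    merge_levels: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where outputs land does not affect results
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def marker_virtual_section(markers: MarkerSet, ds: StratDataset,
                           weight: float = 10.0,
                           section_id: str = "__markers__") -> StratDataset:
    """Fold dated marker events into the dataset as one heavily weighted
    virtual section.

    Marker ages define the level grid (oldest = level 1); taxon markers place
    occurrences at their FAD/LAD levels, and chron boundaries become
    pseudo-taxa pinned to a single level.
    """
    ages = sorted({m.age_ma for m in markers.entries}, reverse=True)
    level_of_age = {a: i + 1 for i, a in enumerate(ages)}
    heights = np.array([ages[0] - a for a in ages])  # ascending, Myr units
    if heights.size > 1 and not np.all(np.diff(heights) > 0):
        raise ValueError("marker ages must be distinct per level")
    occ = set()
    taxa = dict(ds.taxa)
    for m in markers.entries:
        lvl = level_of_age[m.age_ma]
        if m.kind == "chron":
            if m.name not in taxa:
                taxa[m.name] = Taxon(m.name, name=m.name, group="other")
            occ.add((m.name, lvl))
        else:
            if m.name not in ds.taxa:
                raise ValueError(f"marker taxon {m.name!r} absent from dataset")
            occ.add((m.name, lvl))
    vsec = Section(section_id, heights, occ, weight=weight)
    return StratDataset(taxa=taxa, sections=list(ds.sections) + [vsec])


def optimize(ds: StratDataset, cfg: EAConfig, restarts: int = 1):
    """Run the search; for ``restarts > 1``, independent seeded runs are
    merged through a final population seeded from their best sequences."""
    problem = penalty.compile_problem(ds)
    if restarts <= 1:
        return evolve.evolve_run(problem, cfg)
    seqs = []
    for r in range(restarts):
        best, _ = evolve.evolve_run(problem, dataclasses.replace(cfg, seed=cfg.seed + 1000 * r))
        seqs.append(best)
    pop = evolve.init_from_sequences(seqs, problem, cfg)
    return evolve.evolve_run(problem, cfg, population=pop)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
                      "stages": []}

    def fail(stage: str, msg: str):
        _write_manifest(manifest, out)
        raise PipelineError(stage, msg)

    # stage 1: load, screen, connectivity
    try:
        ds = dataset.read_sections(cfg.sections_path)
        if cfg.min_events > 0:
            ds = dataset.filter_sections(ds, cfg.min_events)
    except Exception as exc:
        fail("validate", str(exc))
    comps = dataset.connectivity(ds)
    if len(comps) > 1:
        fail("connectivity", f"sections form {len(comps)} disconnected components: "
                             f"{[sorted(c) for c in comps]}")
    manifest["stages"].append("connectivity")
    manifest["n_sections"] = len(ds.sections)
    manifest["n_taxa"] = ds.n_taxa

    # stage 2: virtual marker section
    markers = None
    if cfg.markers_path:
        try:
            markers = calibrate.read_markers(cfg.markers_path)
            ds = marker_virtual_section(markers, ds, weight=cfg.marker_weight)
        except Exception as exc:
            fail("markers", str(exc))
        manifest["stages"].append("markers")

    # stage 3: optimisation
    best, history = optimize(ds, dataclasses.replace(cfg.ea, seed=cfg.ea.seed or cfg.seed),
                             restarts=cfg.restarts)
    problem = penalty.compile_problem(ds)
    penalty.total_penalty(best, problem)
    history.to_csv(out / "history.csv", index=False)
    manifest["stages"].append("optimize")
    manifest["final_penalty"] = float(best.cached_penalty)

    # stage 4: levels + age calibration
    levels = calibrate.cluster_levels(best, problem, merge=cfg.merge_levels)
    manifest["n_levels"] = len(levels)
    age_model = None
    if markers is not None:
        try:
            age_model = calibrate.bootstrap_age_model(
                levels, markers, problem, n_boot=cfg.n_boot_age, seed=cfg.seed)
        except Exception as exc:
            fail("calibrate", str(exc))
        manifest["stages"].append("calibrate")
        manifest["span_myr"] = age_model.span_myr
        manifest["imputed_resolution_kyr"] = calibrate.imputed_resolution(
            age_model.span_myr, len(levels))
        age_model.to_frame().to_csv(out / "age_model.csv", index=False)
    lev_ranks = calibrate.level_of_event(levels, problem.n_events)
    comp_df = best.to_frame(problem)
    comp_df["level"] = lev_ranks[best.order]
    if age_model is not None:
        comp_df["age_ma"] = age_model.level_ages[comp_df["level"]]
    comp_df.to_csv(out / "composite.csv", index=False)

    # diversity stage
    rich = diversity.unbinned_richness(levels, problem, group=cfg.group,
                                       age_model=age_model)
    rich.to_csv(out / "richness.csv", index=False)
    manifest["stages"].append("diversity")
    rates = None
    if age_model is not None:
        rates = diversity.bootstrap_rates(levels, problem, age_model,
                                          bin_width=cfg.bin_width_myr,
                                          group=cfg.group)
        rates.to_csv(out / "rates.csv", index=False)
        for n in cfg.rarefy_sizes:
            rar = diversity.rarefied_series(ds, levels, problem, age_model, n,
                                            bin_width=cfg.bin_width_myr,
                                            seed=cfg.seed)
            rar.to_csv(out / f"rarefied_{n}.csv", index=False)

    # correlation stage
    if cfg.proxy_paths and age_model is not None:
        proxies = [ProxySeries.read(p, name=Path(p).stem) for p in cfg.proxy_paths]
        vals = rich["richness"].to_numpy()
        tables = []
        for dt in (False, True):
            tab = associate.correlation_table(age_model.level_ages, vals, proxies,
                                              grid_step=cfg.bin_width_myr,
                                              n_boot=cfg.n_boot_rho,
                                              seed=cfg.seed, detrend=dt)
            tables.append(tab)
        corr = pd.concat(tables, ignore_index=True)
        corr.to_csv(out / "correlations.csv", index=False)
        manifest["stages"].append("correlate")
        manifest["correlations"] = corr.to_dict("records")

    manifest["seeds"] = {"pipeline": cfg.seed, "ea": cfg.ea.seed}
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    path = out / "manifest.json"
    hashable = dict(manifest)
    cfg = dict(hashable.get("config", {}))
    cfg.pop("out_dir", None)
    hashable["config"] = cfg
    blob = json.dumps(hashable, indent=2, sort_keys=True, default=float)
    manifest["manifest_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
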