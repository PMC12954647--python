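"""End-to-end orchestration: world -> linkage -> tracing -> overlay -> tables.

A run is described by a :class:`RunConfig` (TOML file or kwargs); the
output directory receives one dissolved exposure layer per scenario,
summary CSVs per reporting unit, and a JSON manifest with the config
hash, stage timings and row counts.  Runs on planar synthetic worlds
are bit-identical for identical configs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from shapely.geometry import mapping
from shapely.strtree import STRtree

from . import __version__
from .aggregation import (clean_energy_share, summaries_to_frame,
                          summarize_by_basin, summarize_by_commodity,
                          summarize_by_status, summarize_cpa,
                          summarize_global, summarize_sites)
from .attenuation import AttenuationTable, Scenario, resolve_distance
from .conservation import (COMBINED_CPA, IUCN_CATEGORIZED_PA,
                           buffer_point_sites, build_cpa)
from .hydrography import interval_geometry, validate_network
from .linkage import intersect_rivers, link_mine
from .mines import (DemandShareTable, apply_cluster_statuses, exclude_planned,
                    is_key_etm)
from .tracing import ExposureSet, dissolve, trace_mine
from .synthetic import SyntheticWorld, WorldConfig, generate_world

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (rejected before any work)."""


class MissingInputError(FileNotFoundError):
    """A configured input path does not exist."""


@dataclass
class RunConfig:
    """Pipeline run description; defaults follow the study constants."""

    output_dir: str = "minetrace_out"
    synthetic: Optional[dict] = None      # WorldConfig kwargs
    input_dir: Optional[str] = None       # pre-built world directory
    scenarios: list[str] = field(default_factory=lambda: [
        s.value for s in (Scenario.MODERATE, Scenario.SEVERE)])
    attenuation_csv: Optional[str] = None
    buffer_km: float = 10.0
    limnicity_threshold: float = 20.0
    cpa_variants: list[str] = field(default_factory=lambda: [
        COMBINED_CPA, IUCN_CATEGORIZED_PA])
    mode: str = "planar"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.buffer_km <= 0:
            raise ConfigError("buffer_km must be positive")
        if not (0.0 <= self.limnicity_threshold <= 100.0):
            raise ConfigError("limnicity_threshold must be in [0, 100]")
        for s in self.scenarios:
            try:
                Scenario(s)
            except ValueError:
                raise ConfigError(f"unknown scenario {s!r}") from None
        for v in self.cpa_variants:
            if v not in (COMBINED_CPA, IUCN_CATEGORIZED_PA):
                raise ConfigError(f"unknown CPA variant {v!r}")
        if self.synthetic is None and self.input_dir is None:
            raise ConfigError("either synthetic world config or input_dir "
                              "is required")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise MissingInputError(self.input_dir)
        if (self.attenuation_csv is not None
                and not Path(self.attenuation_csv).exists()):
            raise MissingInputError(self.attenuation_csv)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        if not Path(path).exists():
            raise MissingInputError(str(path))
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_world(directory: str | Path, mode: str = "planar") -> SyntheticWorld:
    """Load a world directory written by :func:`minetrace.geoio.write_world`."""
    from . import geoio  # deferred: geoio imports nothing from here
    directory = Path(directory)
    if not directory.exists():
        raise MissingInputError(str(directory))
    meta = json.loads((directory / "world.json").read_text())
    mode = meta.get("mode", mode)
    network = geoio.read_rivers(directory / "rivers.geojson", mode=mode)
    report = validate_network(network)
    if not report.ok:
        raise ValueError(f"invalid river network: {report}")
    return SyntheticWorld(
        config=WorldConfig(seed=meta.get("seed", 0), mode=mode,
                           buffer_km=meta.get("buffer_km", 10.0),
                           limnicity_threshold=meta.get(
                               "limnicity_threshold", 20.0)),
        network=network,
        grid=geoio.read_grid(directory),
        mines=geoio.read_mines(directory / "mines.geojson"),
        clusters=geoio.read_clusters(directory / "clusters.json"),
        pa_sites=geoio.read_sites(directory / "sites_pa.geojson"),
        kba_sites=geoio.read_sites(directory / "sites_kba.geojson"),
        attenuation=AttenuationTable(
            element_specific=meta.get("element_distances_km", {})),
        ground_truth={})


def write_exposure_layer(exposure: ExposureSet, network, path: Path) -> None:
    feats = []
    for reach in exposure.reaches:
        iv = reach.interval
        feats.append({
            "type": "Feature",
            "geometry": mapping(interval_geometry(network, iv)),
            "properties": {
                "segment_id": iv.segment_id,
                "start_km": iv.start_km,
                "end_km": iv.end_km,
                "length_km": iv.length_km,
                "commodities": ",".join(sorted(reach.commodities)),
                "statuses": ",".join(sorted(reach.statuses)),
                "n_mines": len(reach.sources),
                "direct": reach.direct,
                "scenario": exposure.scenario.value,
            }})
    path.write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the output directory."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # world
    if config.synthetic is not None:
        world = generate_world(WorldConfig(**config.synthetic))
    else:
        world = load_world(config.input_dir, mode=config.mode)
    net, grid = world.network, world.grid
    timings["world"] = time.perf_counter() - t0

    # mines: harmonize + exclude planned
    t = time.perf_counter()
    mines = apply_cluster_statuses(world.mines, world.clusters)
    mines, n_planned = exclude_planned(mines)
    timings["harmonize"] = time.perf_counter() - t

    # linkage
    t = time.perf_counter()
    order = list(net.segments)
    tree = STRtree([net[s].geometry for s in order])
    entries, directs = {}, {}
    for mine in mines:
        entries[mine.mine_id] = link_mine(
            mine, grid, net, max_km=config.buffer_km, mode=world.config.mode)
        directs[mine.mine_id] = intersect_rivers(
            mine, net, tree=tree, segment_order=order)
    n_linked = sum(1 for m in mines
                   if entries[m.mine_id] or directs[m.mine_id].intervals)
    timings["link"] = time.perf_counter() - t

    # attenuation
    if config.attenuation_csv is not None:
        table = AttenuationTable.from_csv(config.attenuation_csv)
    else:
        table = world.attenuation
    demand = DemandShareTable()

    # CPA layers
    t = time.perf_counter()
    pa = buffer_point_sites(world.pa_sites, mode=world.config.mode)
    kba = buffer_point_sites(world.kba_sites, mode=world.config.mode)
    cpas = {v: build_cpa(pa, kba, variant=v) for v in config.cpa_variants}
    timings["cpa"] = time.perf_counter() - t

    all_rows = []
    mode = world.config.mode
    for name in config.scenarios:
        t = time.perf_counter()
        scenario = Scenario(name)
        per_mine = []
        for mine in mines:
            distance = resolve_distance(mine.commodities, table, scenario)
            per_mine.extend(trace_mine(
                net, mine, entries[mine.mine_id], directs[mine.mine_id],
                distance, config.limnicity_threshold))
        exposure = ExposureSet(reaches=per_mine, scenario=scenario)
        dissolved = dissolve(exposure)
        write_exposure_layer(dissolved, net,
                             out_dir / f"exposure_{name}.geojson")

        rows = [summarize_global(dissolved, net)]
        rows += summarize_by_commodity(per_mine, net, scenario)
        rows += summarize_by_basin(dissolved, net)
        rows += summarize_by_status(per_mine, net, scenario)
        etm = [r for r in per_mine if is_key_etm(r.commodities)]
        if etm:
            weighted, unweighted = clean_energy_share(etm, demand, scenario)
            for row in rows:
                if row.unit_kind == "commodity" and row.unit_id == "key_etm":
                    row.clean_energy_km = weighted
        for variant, cpa in cpas.items():
            rows.append(summarize_cpa(dissolved, net, cpa, mode=mode))
            rows += summarize_sites(dissolved, net, cpa, mode=mode) \
                if variant == COMBINED_CPA else []
        all_rows.extend(rows)
        timings[f"scenario_{name}"] = time.perf_counter() - t

    frame = summaries_to_frame(all_rows)
    for kind in sorted(frame["unit_kind"].unique()):
        sub = frame[frame["unit_kind"] == kind].sort_values(
            ["unit_id", "scenario"])
        sub.to_csv(out_dir / f"summary_{kind}.csv", index=False)

    cfg_dict = asdict(config)
    manifest = {
        "package_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "n_segments": len(net),
        "n_mines": len(mines),
        "n_planned_removed": n_planned,
        "n_linked": n_linked,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
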