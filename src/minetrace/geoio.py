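"""Readers and writers for the package's on-disk formats.

Vector layers are GeoJSON FeatureCollections (attribute column names
mapped through small config dicts, HydroRIVERS/WDPA-style columns by
default); rasters are ESRI ASCII grids (plain text), with the stream
mask's integer cell values indexed into a JSON sidecar of segment ids.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
from shapely.geometry import mapping, shape

from .conservation import ConservationSite
from .hydrography import FlowGrid, RiverNetwork, RiverSegment, orient_segments
from .mines import MineCluster, MinePolygon, canonicalize_commodities

RIVER_COLUMNS = {
    "segment_id": "HYRIV_ID",
    "downstream_id": "NEXT_DOWN",
    "length_km": "LENGTH_KM",
    "limnicity_pct": "LIMNICITY",
    "basin_id": "MAIN_BAS",
    "discharge_m3s": "DIS_AV_CMS",
}

MINE_COLUMNS = {
    "mine_id": "mine_id",
    "cluster_id": "cluster_id",
    "commodities": "commodities_list",
    "status": "status",
}

SITE_COLUMNS = {
    "site_id": "site_id",
    "layer": "layer",
    "reported_area_km2": "rep_area_km2",
    "designation_type": "desig_type",
    "iucn_category": "iucn_cat",
    "status_flag": "status",
    "marine": "marine",
}


class SchemaError(KeyError):
    """A required attribute column is missing from an input layer."""


def _features(path: str | Path) -> list[dict]:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise SchemaError(f"{path} is not a GeoJSON FeatureCollection")
    return data["features"]


def _collection(features: Iterable[dict]) -> dict:
    return {"type": "FeatureCollection", "features": list(features)}


def _get(props: Mapping, colmap: Mapping[str, str], key: str, required=True):
    col = colmap[key]
    if col in props:
        return props[col]
    if required:
        raise SchemaError(f"missing column {col!r} (for {key})")
    return None


# --- rivers -----------------------------------------------------------------

def read_rivers(path: str | Path, colmap: Mapping[str, str] = RIVER_COLUMNS,
                mode: str = "planar") -> RiverNetwork:
    segments = []
    for feat in _features(path):
        props = feat["properties"]
        down = _get(props, colmap, "downstream_id")
        limnicity = _get(props, colmap, "limnicity_pct", required=False)
        discharge = _get(props, colmap, "discharge_m3s", required=False)
        length = _get(props, colmap, "length_km", required=False)
        segments.append(RiverSegment(
            segment_id=str(_get(props, colmap, "segment_id")),
            geometry=shape(feat["geometry"]),
            downstream_id=str(down) if down not in (None, "", 0) else None,
            limnicity_pct=float(limnicity or 0.0),
            basin_id=str(_get(props, colmap, "basin_id")),
            length_km=float(length) if length is not None else None,
            discharge_m3s=float(discharge) if discharge is not None else None))
    return RiverNetwork(orient_segments(segments), mode=mode)


def write_rivers(network: RiverNetwork, path: str | Path,
                 colmap: Mapping[str, str] = RIVER_COLUMNS) -> None:
    feats = []
    for seg in network.segments.values():
        feats.append({
            "type": "Feature",
            "geometry": mapping(seg.geometry),
            "properties": {
                colmap["segment_id"]: seg.segment_id,
                colmap["downstream_id"]: seg.downstream_id or "",
                colmap["length_km"]: seg.length_km,
                colmap["limnicity_pct"]: seg.limnicity_pct,
                colmap["basin_id"]: seg.basin_id,
                colmap["discharge_m3s"]: seg.discharge_m3s,
            }})
    Path(path).write_text(json.dumps(_collection(feats)))


# --- mines ------------------------------------------------------------------

def read_mines(path: str | Path, colmap: Mapping[str, str] = MINE_COLUMNS,
               delimiter: str = ",") -> list[MinePolygon]:
    out = []
    for feat in _features(path):
        props = feat["properties"]
        raw = _get(props, colmap, "commodities", required=False) or ""
        status = _get(props, colmap, "status", required=False) or "unknown"
        out.append(MinePolygon(
            mine_id=str(_get(props, colmap, "mine_id")),
            cluster_id=str(_get(props, colmap, "cluster_id")),
            geometry=shape(feat["geometry"]),
            commodities=canonicalize_commodities(raw, delimiter=delimiter),
            status=str(status)))
    return out


def write_mines(mines: Iterable[MinePolygon], path: str | Path,
                colmap: Mapping[str, str] = MINE_COLUMNS) -> None:
    feats = [{
        "type": "Feature",
        "geometry": mapping(m.geometry),
        "properties": {
            colmap["mine_id"]: m.mine_id,
            colmap["cluster_id"]: m.cluster_id,
            colmap["commodities"]: ",".join(sorted(m.commodities)),
            colmap["status"]: m.status,
        }} for m in mines]
    Path(path).write_text(json.dumps(_collection(feats)))


def read_clusters(path: str | Path) -> list[MineCluster]:
    with open(path) as fh:
        data = json.load(fh)
    return [MineCluster(cluster_id=cid, member_ids=rec["members"],
                        point_statuses=rec["point_statuses"])
            for cid, rec in sorted(data.items())]


def write_clusters(clusters: Iterable[MineCluster], path: str | Path) -> None:
    data = {c.cluster_id: {"members": c.member_ids,
                           "point_statuses": c.point_statuses}
            for c in clusters}
    Path(path).write_text(json.dumps(data, indent=1))


# --- conservation sites ------------------------------------------------------

def read_sites(path: str | Path, colmap: Mapping[str, str] = SITE_COLUMNS
               ) -> list[ConservationSite]:
    out = []
    for feat in _features(path):
        props = feat["properties"]
        iucn = _get(props, colmap, "iucn_category", required=False)
        out.append(ConservationSite(
            site_id=str(_get(props, colmap, "site_id")),
            layer=str(_get(props, colmap, "layer")),
            geometry=shape(feat["geometry"]),
            reported_area_km2=float(
                _get(props, colmap, "reported_area_km2", required=False) or 0.0),
            designation_type=str(
                _get(props, colmap, "designation_type", required=False)
                or "national"),
            iucn_category=str(iucn) if iucn else None,
            status_flag=str(_get(props, colmap, "status_flag", required=False)
                            or "designated"),
            marine=bool(_get(props, colmap, "marine", required=False))))
    return out


def write_sites(sites: Iterable[ConservationSite], path: str | Path,
                colmap: Mapping[str, str] = SITE_COLUMNS) -> None:
    feats = [{
        "type": "Feature",
        "geometry": mapping(s.geometry),
        "properties": {
            colmap["site_id"]: s.site_id,
            colmap["layer"]: s.layer,
            colmap["reported_area_km2"]: s.reported_area_km2,
            colmap["designation_type"]: s.designation_type,
            colmap["iucn_category"]: s.iucn_category or "",
            colmap["status_flag"]: s.status_flag,
            colmap["marine"]: s.marine,
        }} for s in sites]
    Path(path).write_text(json.dumps(_collection(feats)))


# --- rasters ----------------------------------------------------------------

def write_ascii_grid(array: np.ndarray, path: str | Path, x_origin: float,
                     y_origin_top: float, cell_size: float,
                     nodata: int = -9999) -> None:
    """ESRI ASCII grid; note yllcorner is the SOUTH edge."""
    nrow, ncol = array.shape
    header = (f"ncols {ncol}\nnrows {nrow}\n"
              f"xllcorner {x_origin}\n"
              f"yllcorner {y_origin_top - nrow * cell_size}\n"
              f"cellsize {cell_size}\nNODATA_value {nodata}\n")
    body = "\n".join(" ".join(str(int(v)) for v in row) for row in array)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    """Returns (array, x_origin, y_origin_top, cell_size)."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value"):
        key, val = lines[i].split()
        header[key.lower()] = float(val)
        i += 1
    array = np.array([[int(v) for v in line.split()] for line in lines[i:]
                      if line.strip()], dtype=np.int32)
    cell = header["cellsize"]
    y_top = header["yllcorner"] + header["nrows"] * cell
    return array, header["xllcorner"], y_top, cell


def write_grid(grid: FlowGrid, directory: str | Path) -> None:
    directory = Path(directory)
    write_ascii_grid(grid.direction, directory / "d8.asc", grid.x_origin,
                     grid.y_origin, grid.cell_size)
    write_ascii_grid(grid.stream_index, directory / "streams.asc",
                     grid.x_origin, grid.y_origin, grid.cell_size, nodata=-1)
    (directory / "streams_index.json").write_text(
        json.dumps(grid.segment_ids))


def read_grid(directory: str | Path,
              codes: Optional[Mapping[int, tuple[int, int]]] = None,
              sink_code: int = 0) -> FlowGrid:
    directory = Path(directory)
    direction, x0, y0, cell = read_ascii_grid(directory / "d8.asc")
    stream_index, *_ = read_ascii_grid(directory / "streams.asc")
    segment_ids = json.loads((directory / "streams_index.json").read_text())
    kwargs = {"codes": dict(codes)} if codes is not None else {}
    return FlowGrid(direction=direction, stream_index=stream_index,
                    segment_ids=segment_ids, x_origin=x0, y_origin=y0,
                    cell_size=cell, sink_code=sink_code, **kwargs)


# --- whole worlds ------------------------------------------------------------

def write_world(world, directory: str | Path) -> None:
    """Persist a synthetic world in the same formats the loaders read."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_rivers(world.network, directory / "rivers.geojson")
    write_mines(world.mines, directory / "mines.geojson")
    write_clusters(world.clusters, directory / "clusters.json")
    write_sites(world.pa_sites, directory / "sites_pa.geojson")
    write_sites(world.kba_sites, directory / "sites_kba.geojson")
    write_grid(world.grid, directory)
    meta = {"mode": world.config.mode, "seed": world.config.seed,
            "buffer_km": world.config.buffer_km,
            "limnicity_threshold": world.config.limnicity_threshold,
            "element_distances_km": world.attenuation.element_specific}
    (directory / "world.json").write_text(json.dumps(meta, indent=1))
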