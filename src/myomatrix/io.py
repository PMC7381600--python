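"""File formats: TIFF label volumes with sidecar metadata, node-link
graph JSON, event and metric CSV tables, track JSON-lines, and the
key=value configuration format used by the command-line interface.

All writers round-trip losslessly through their readers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .extract import BranchEvent, MyoGraph, MyoNode, SegmentationBundle
from .metrics import VolumeMetrics
from .tracking import MyofibrilTrack

__all__ = [
    "write_bundle",
    "read_bundle",
    "write_graph",
    "read_graph",
    "write_events",
    "read_events",
    "write_tracks",
    "read_tracks",
    "write_metrics",
    "read_metrics",
    "read_config",
]


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    ay, ax = axes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def write_bundle(bundle: SegmentationBundle, volume_path, meta_path) -> None:
    """Write a bundle as multi-page 16-bit TIFF plus JSON sidecar metadata."""
    volume_path, meta_path = Path(volume_path), Path(meta_path)
    vol = np.ascontiguousarray(bundle.label_volume.astype(np.uint16))
    tifffile.imwrite(volume_path, vol, photometric="minisblack")
    meta = {
        "n_slices": int(bundle.n_slices),
        "shape": list(vol.shape),
        "z_disk_slices": [int(z) for z in bundle.z_disk_slices],
        "voxel_pitch_nm": float(bundle.voxel_pitch_nm),
        "metadata": _jsonable(bundle.metadata),
    }
    if "cell_axes_vox" in bundle.metadata and "cell_center" in bundle.metadata:
        meta["cell_mask"] = {
            "type": "ellipse",
            "center": list(bundle.metadata["cell_center"]),
            "axes": list(bundle.metadata["cell_axes_vox"]),
        }
    else:
        mask_path = volume_path.with_suffix(".mask.tif")
        tifffile.imwrite(mask_path, bundle.cell_mask.astype(np.uint8))
        meta["cell_mask"] = {"type": "tiff", "path": mask_path.name}
    meta_path.write_text(json.dumps(meta, indent=1))


def read_bundle(volume_path, meta_path) -> SegmentationBundle:
    """Read a bundle written by :func:`write_bundle`, validating shapes."""
    volume_path, meta_path = Path(volume_path), Path(meta_path)
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed metadata file {meta_path}: {exc}") from exc
    for key in ("n_slices", "z_disk_slices", "voxel_pitch_nm", "cell_mask"):
        if key not in meta:
            raise ValueError(f"metadata file {meta_path} missing field {key!r}")
    vol = tifffile.imread(volume_path)
    if vol.ndim == 2:
        vol = vol[None]
    if vol.shape[0] != meta["n_slices"]:
        raise ValueError(
            f"volume {volume_path} has {vol.shape[0]} slices but metadata "
            f"{meta_path} declares {meta['n_slices']} (truncated file?)"
        )
    cm = meta["cell_mask"]
    if cm["type"] == "ellipse":
        mask = _ellipse_mask(vol.shape[1:], cm["center"], cm["axes"])
    elif cm["type"] == "tiff":
        mask = tifffile.imread(volume_path.parent / cm["path"]).astype(bool)
    else:
        raise ValueError(f"unknown cell_mask type {cm['type']!r} in {meta_path}")
    return SegmentationBundle(
        label_volume=vol,
        z_disk_slices=np.asarray(meta["z_disk_slices"], int),
        cell_mask=mask,
        voxel_pitch_nm=meta["voxel_pitch_nm"],
        metadata=meta.get("metadata", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _event_to_dict(e: BranchEvent) -> dict:
    d = dataclasses.asdict(e)
    d.pop("render", None)
    d["parents"] = list(e.parents)
    d["children"] = list(e.children)
    return d


def _event_from_dict(d: dict) -> BranchEvent:
    d = dict(d)
    d["parents"] = tuple(d["parents"])
    d["children"] = tuple(d["children"])
    d.setdefault("render", None)
    return BranchEvent(**d)


def write_graph(graph: MyoGraph, path) -> None:
    """Serialize a graph as node-link JSON."""
    doc = {
        "nodes": [dataclasses.asdict(n) for n in graph.nodes],
        "serial_edges": [list(e) for e in graph.serial_edges],
        "events": [_event_to_dict(e) for e in graph.events],
        "n_intervals": graph.n_intervals,
        "z_disk_slices": [int(z) for z in graph.z_disk_slices],
        "meta": _jsonable(graph.meta),
    }
    Path(path).write_text(json.dumps(doc))


def read_graph(path) -> MyoGraph:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed graph file {path}: {exc}") from exc
    for key in ("nodes", "serial_edges", "events", "n_intervals", "z_disk_slices"):
        if key not in doc:
            raise ValueError(f"graph file {path} missing field {key!r}")
    nodes = []
    for nd in doc["nodes"]:
        nd["centroid"] = tuple(nd["centroid"])
        nodes.append(MyoNode(**nd))
    return MyoGraph(
        nodes=nodes,
        serial_edges=[tuple(e) for e in doc["serial_edges"]],
        events=[_event_from_dict(d) for d in doc["events"]],
        n_intervals=doc["n_intervals"],
        z_disk_slices=np.asarray(doc["z_disk_slices"], int),
        meta=doc.get("meta", {}),
    )


_EVENT_COLUMNS = [
    "event_id",
    "type",
    "slice_index",
    "interval",
    "phase_fraction",
    "band",
    "parents",
    "children",
    "donor",
    "acceptor",
    "donor_cont",
    "acceptor_cont",
]


def write_events(events, path) -> None:
    """Event table as CSV; multi-label fields are '|'-joined."""
    rows = []
    for e in events:
        d = _event_to_dict(e)
        d["parents"] = "|".join(str(p) for p in e.parents)
        d["children"] = "|".join(str(c) for c in e.children)
        rows.append({k: d.get(k) for k in _EVENT_COLUMNS})
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path) -> list[BranchEvent]:
    df = pd.read_csv(path)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table {path} missing columns {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        d["parents"] = tuple(int(x) for x in str(d["parents"]).split("|"))
        d["children"] = tuple(int(x) for x in str(d["children"]).split("|"))
        for k in ("donor", "acceptor", "donor_cont", "acceptor_cont"):
            d[k] = None if pd.isna(d[k]) else int(d[k])
        if pd.isna(d["band"]):
            d["band"] = None
        d["event_id"] = int(d["event_id"])
        d["slice_index"] = int(d["slice_index"])
        d["interval"] = int(d["interval"])
        events.append(_event_from_dict(d))
    return events


def write_tracks(tracks, path) -> None:
    """Tracks as JSON lines, one track per line."""
    with open(path, "w") as fh:
        for t in tracks:
            fh.write(json.dumps(dataclasses.asdict(t)) + "\n")


def read_tracks(path) -> list[MyofibrilTrack]:
    tracks = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        d["events"] = [tuple(e) for e in d["events"]]
        tracks.append(MyofibrilTrack(**d))
    return tracks


def write_metrics(metrics_list, path) -> None:
    """One CSV row per volume."""
    rows = [dataclasses.asdict(m) for m in metrics_list]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "volume_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"metrics table {path} lacks volume_id/group columns")
    return df


def read_config(path) -> dict:
    """Declarative key=value configuration; '#' starts a comment."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected key=value, got {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = val
    return out
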