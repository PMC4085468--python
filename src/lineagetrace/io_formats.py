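"""Readers and writers: detection tables, lineage CSV, Newick, JSON models.

All writers are deterministic (fixed column order, shortest round-trip
float formatting), so identical inputs give byte-identical outputs and
``read_lineage(write_lineage(L)) == L`` exactly.

Voxel anisotropy is applied exactly once, here: ``read_detections`` scales
x/y by ``xy_resolution`` and z by ``z_resolution`` so that everything
downstream works in isotropic microns.
"""

from __future__ import annotations

import csv
import json
import zipfile
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from lineagetrace.classify import NBModel
from lineagetrace.model import (Detection, Lineage, STATUS_TRACKED, Track,
                                TrackingConfig, tracks_of)
from lineagetrace.simulate import SimConfig

PathLike = Union[str, Path]

DETECTION_COLUMNS = ("t", "x", "y", "z", "radius", "intensity")


class FormatError(ValueError):
    """Malformed input file."""


def _fmt(v: float) -> str:
    """Deterministic shortest representation that parses back exactly."""
    return repr(float(v))


# ---------------------------------------------------------------------------
# detection tables


def read_detections(path: PathLike, config: TrackingConfig) -> List[Detection]:
    """Read a voxel-unit detection CSV and scale coordinates to microns.

    Required columns: t,x,y,z,radius,intensity; optional: eccentricity.
    Ids are assigned deterministically in file order (1-based).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header")
        for col in DETECTION_COLUMNS:
            if col not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column {col!r}")
        has_ecc = "eccentricity" in reader.fieldnames
        out: List[Detection] = []
        for i, row in enumerate(reader, start=1):
            try:
                t = int(row["t"])
                x = float(row["x"]) * config.xy_resolution
                y = float(row["y"]) * config.xy_resolution
                z = float(row["z"]) * config.z_resolution
                radius = float(row["radius"]) * config.xy_resolution
                intensity = float(row["intensity"])
                ecc = None
                if has_ecc and row["eccentricity"] not in ("", None):
                    ecc = float(row["eccentricity"])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: non-numeric value in data row {i}") from exc
            out.append(Detection(id=i, t=t, x=x, y=y, z=z, radius=radius,
                                 intensity=intensity, eccentricity=ecc))
    return out


def write_detections(detections: Sequence[Detection], path: PathLike) -> None:
    """Micron-unit detection CSV (id column included for provenance)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("id", "t", "x", "y", "z", "radius", "intensity", "eccentricity"))
        for d in sorted(detections, key=lambda d: (d.t, d.id)):
            w.writerow((d.id, d.t, _fmt(d.x), _fmt(d.y), _fmt(d.z), _fmt(d.radius),
                        _fmt(d.intensity),
                        "" if d.eccentricity is None else _fmt(d.eccentricity)))


def read_detections_microns(path: PathLike) -> List[Detection]:
    """Read a micron-unit detection CSV written by :func:`write_detections`."""
    path = Path(path)
    out: List[Detection] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=1):
            try:
                ecc = row.get("eccentricity")
                out.append(Detection(
                    id=int(row["id"]) if "id" in row else i,
                    t=int(row["t"]), x=float(row["x"]), y=float(row["y"]),
                    z=float(row["z"]), radius=float(row["radius"]),
                    intensity=float(row["intensity"]),
                    eccentricity=float(ecc) if ecc not in ("", None) else None))
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: non-numeric value in data row {i}") from exc
    return out


# ---------------------------------------------------------------------------
# lineage CSV


def write_lineage(lineage: Lineage, path: PathLike) -> None:
    """One row per detection, deleted rows retained with their flag."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("id", "t", "x", "y", "z", "radius", "intensity",
                    "eccentricity", "pred_id", "succ1_id", "succ2_id", "status"))
        for det_id in sorted(lineage.detections):
            d = lineage.detections[det_id]
            pred = lineage.predecessor(det_id)
            succ = list(lineage.successors(det_id)) + [None, None]
            w.writerow((
                d.id, d.t, _fmt(d.x), _fmt(d.y), _fmt(d.z), _fmt(d.radius),
                _fmt(d.intensity),
                "" if d.eccentricity is None else _fmt(d.eccentricity),
                -1 if pred is None else pred,
                -1 if succ[0] is None else succ[0],
                -1 if succ[1] is None else succ[1],
                lineage.status[det_id],
            ))


def read_lineage(path: PathLike) -> Lineage:
    path = Path(path)
    lineage = Lineage()
    links = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=1):
            try:
                ecc = row.get("eccentricity")
                det = Detection(
                    id=int(row["id"]), t=int(row["t"]), x=float(row["x"]),
                    y=float(row["y"]), z=float(row["z"]), radius=float(row["radius"]),
                    intensity=float(row["intensity"]),
                    eccentricity=float(ecc) if ecc not in ("", None) else None)
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: bad value in data row {i}") from exc
            lineage.add_detection(det, status=row["status"])
            pred = int(row["pred_id"])
            if pred != -1:
                links.append((pred, det.id))
    for pred, succ in links:
        lineage.add_link(pred, succ)
    return lineage


# ---------------------------------------------------------------------------
# Newick export


def export_newick(lineage: Lineage, root_id: int) -> str:
    """Newick tree of the tracks reachable from the track containing root_id.

    Branch lengths are track durations in frames; leaf/internal labels are
    "T<first detection id>" of the corresponding track.
    """
    if root_id not in lineage.detections:
        raise KeyError(f"root detection {root_id} not found")
    track_by_first: Dict[int, Track] = {t.first_id: t for t in tracks_of(lineage)}
    track_of_det: Dict[int, Track] = {}
    for tr in track_by_first.values():
        for det_id in tr.detection_ids:
            track_of_det[det_id] = tr
    root = track_of_det.get(root_id)
    if root is None:
        raise KeyError(f"root detection {root_id} is deleted")

    def render(tr: Track) -> str:
        label = f"T{tr.first_id}"
        kids = lineage.successors(tr.last_id)
        if len(kids) == 2:
            parts = ",".join(render(track_of_det[k]) for k in sorted(kids))
            return f"({parts}){label}:{tr.length}"
        return f"{label}:{tr.length}"

    return render(root) + ";"


# ---------------------------------------------------------------------------
# AceTree-style "nuclei" files (read-only, minimal shared fields)


def read_nuclei_zip(path: PathLike, config: TrackingConfig) -> List[Detection]:
    """Read per-timepoint ``*-nuclei`` text files from a zip archive.

    Only the minimal shared fields are used: column 0 is the per-frame
    index, column 1 a validity flag, columns 5-7 the voxel x/y/z and
    column 8 the diameter; the first numeric column after the diameter
    (the dialects place a cell name in between) is read as intensity.
    Frame order follows the sorted member names.
    """
    out: List[Detection] = []
    next_id = 1
    with zipfile.ZipFile(path) as zf:
        names = sorted(n for n in zf.namelist() if n.endswith("-nuclei"))
        for t, name in enumerate(names, start=1):
            text = zf.read(name).decode("utf-8", errors="replace")
            for line in text.splitlines():
                parts = [p.strip() for p in line.split(",")]
                if len(parts) < 9 or not parts[0]:
                    continue
                try:
                    valid = int(parts[1])
                    if valid == 0:
                        continue
                    x = float(parts[5]) * config.xy_resolution
                    y = float(parts[6]) * config.xy_resolution
                    z = float(parts[7]) * config.z_resolution
                    diameter = float(parts[8]) * config.xy_resolution
                except ValueError:
                    continue
                intensity = 0.0
                for field in parts[9:12]:
                    try:
                        intensity = float(field)
                        break
                    except ValueError:
                        continue
                out.append(Detection(id=next_id, t=t, x=x, y=y, z=z,
                                     radius=max(diameter / 2.0, 1e-9),
                                     intensity=max(intensity, 0.0)))
                next_id += 1
    return out


# ---------------------------------------------------------------------------
# JSON model / config


def write_model(model: NBModel, path: PathLike) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True) + "\n")


def read_model(path: PathLike) -> NBModel:
    return NBModel.from_dict(json.loads(Path(path).read_text()))


def write_config(path: PathLike, tracking: Optional[TrackingConfig] = None,
                 simulation: Optional[SimConfig] = None) -> None:
    doc = {}
    if tracking is not None:
        doc["tracking"] = tracking.to_dict()
    if simulation is not None:
        doc["simulation"] = simulation.to_dict()
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_config(path: PathLike) -> Dict[str, object]:
    doc = json.loads(Path(path).read_text())
    out: Dict[str, object] = {}
    if "tracking" in doc:
        out["tracking"] = TrackingConfig.from_dict(doc["tracking"])
    if "simulation" in doc:
        out["simulation"] = SimConfig.from_dict(doc["simulation"])
    return out
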