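"""File formats for per-frame proxemic data and group annotations.

The canonical interchange format is JSON::

    {"unit": "cm",
     "frames": [{"id": 0,
                 "persons": [{"id": 0, "x": 0.0, "y": 0.0, "theta": 0.0}, ...],
                 "groups": [[0, 1], [2, 3, 4]]}, ...]}

``groups`` is optional per frame and lists only groups of cardinality
>= 2; everyone else is a singleton.  The CSV flavour uses one row per
person (``frame_id, person_id, x, y, theta``) with an optional sibling
groups file (``frame_id, group_index, person_id``).  A best-effort
reader for the published MATLAB benchmark layout (per-frame feature
cell arrays) is provided for convenience; it logs any fields it cannot
map rather than guessing silently.

Angles are radians by default; pass ``degrees=True`` to convert once
on ingest.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GroupSet, PersonState, Scene

__all__ = ["FrameFile", "SchemaError", "read_scenes", "write_scenes", "PRESETS"]

logger = logging.getLogger("gcff")


class SchemaError(ValueError):
    """Raised when an input file does not match the documented schema."""


# Per-dataset parameter presets (stride D, sigma) for the five public
# benchmarks; units are centimetres or pixels depending on the dataset.
PRESETS: dict[str, dict[str, float]] = {
    "synthetic": {"stride_D": 30.0, "sigma": 80.0},
    "idiap": {"stride_D": 20.0, "sigma": 45.0},
    "cocktail": {"stride_D": 70.0, "sigma": 170.0},
    "coffeebreak": {"stride_D": 30.0, "sigma": 85.0},
    "gdet": {"stride_D": 30.0, "sigma": 200.0},
}


@dataclass
class FrameFile:
    """An ordered collection of frames with optional ground truth."""

    frames: list[tuple] = field(default_factory=list)  # (frame_id, Scene)
    unit: str = "cm"

    def scenes(self) -> list[Scene]:
        return [scene for _, scene in self.frames]

    def truth_sets(self) -> list[GroupSet | None]:
        return [scene.truth for _, scene in self.frames]


def _coerce_number(value, what: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric {what}: {value!r}") from exc
    if not math.isfinite(out):
        raise SchemaError(f"non-finite {what}: {value!r}")
    return out


def _person_from_record(rec: dict, degrees: bool) -> PersonState:
    for key in ("id", "x", "y", "theta"):
        if key not in rec:
            raise SchemaError(f"person record missing field {key!r}: {rec!r}")
    theta = _coerce_number(rec["theta"], "theta")
    if degrees:
        theta = math.radians(theta)
    return PersonState(
        rec["id"],
        _coerce_number(rec["x"], "x"),
        _coerce_number(rec["y"], "y"),
        theta,
    )


def _truth_from_lists(group_lists, person_ids) -> GroupSet:
    groups = []
    grouped: set = set()
    for members in group_lists:
        g = frozenset(members)
        if len(g) < 2:
            raise SchemaError(f"annotated group with < 2 members: {sorted(members)!r}")
        unknown = g - set(person_ids)
        if unknown:
            raise SchemaError(f"group references unknown person ids: {sorted(unknown, key=repr)}")
        groups.append(g)
        grouped |= g
    singles = frozenset(pid for pid in person_ids if pid not in grouped)
    return GroupSet(groups=tuple(groups), singletons=singles)


# ---------------------------------------------------------------------------
# JSON


def _read_json(path: Path, degrees: bool) -> FrameFile:
    with open(path) as fh:
        doc = json.load(fh)
    if "frames" not in doc:
        raise SchemaError("top-level 'frames' field missing")
    unit = doc.get("unit", "cm")
    out = FrameFile(unit=unit)
    seen_ids: set = set()
    for frame in doc["frames"]:
        if "id" not in frame or "persons" not in frame:
            raise SchemaError("frame missing 'id' or 'persons'")
        fid = frame["id"]
        if fid in seen_ids:
            raise SchemaError(f"duplicate frame id {fid!r}")
        seen_ids.add(fid)
        persons = tuple(_person_from_record(r, degrees) for r in frame["persons"])
        ids = [p.id for p in persons]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"duplicate person ids in frame {fid!r}")
        truth = (
            _truth_from_lists(frame["groups"], ids) if "groups" in frame else None
        )
        out.frames.append((fid, Scene(persons=persons, truth=truth, unit=unit)))
    return out


def _write_json(ff: FrameFile, path: Path) -> None:
    frames = []
    for fid, scene in ff.frames:
        rec = {
            "id": fid,
            "persons": [
                {"id": p.id, "x": p.x, "y": p.y, "theta": p.theta} for p in scene
            ],
        }
        if scene.truth is not None:
            rec["groups"] = scene.truth.as_lists()
        frames.append(rec)
    doc = {"unit": ff.unit, "frames": frames}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# CSV


def _groups_path(path: Path) -> Path:
    return path.with_name(path.stem + "_groups" + path.suffix)


def _read_csv(path: Path, degrees: bool) -> FrameFile:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame_id", "person_id", "x", "y", "theta"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"CSV missing columns: {sorted(missing)}")
    gpath = _groups_path(path)
    gdf = None
    if gpath.exists():
        gdf = pd.read_csv(gpath)
        gmissing = {"frame_id", "group_index", "person_id"} - set(gdf.columns)
        if gmissing:
            raise SchemaError(f"groups CSV missing columns: {sorted(gmissing)}")
    out = FrameFile(unit="cm")
    for fid, sub in df.groupby("frame_id", sort=True):
        persons = tuple(
            _person_from_record(
                {"id": r.person_id, "x": r.x, "y": r.y, "theta": r.theta}, degrees
            )
            for r in sub.itertuples()
        )
        ids = [p.id for p in persons]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"duplicate person ids in frame {fid!r}")
        truth = None
        if gdf is not None:
            gsub = gdf[gdf["frame_id"] == fid]
            lists = [
                g["person_id"].tolist() for _, g in gsub.groupby("group_index")
            ]
            truth = _truth_from_lists(lists, ids)
        out.frames.append((fid, Scene(persons=persons, truth=truth, unit="cm")))
    return out


def _write_csv(ff: FrameFile, path: Path) -> None:
    rows = [
        {"frame_id": fid, "person_id": p.id, "x": p.x, "y": p.y, "theta": p.theta}
        for fid, scene in ff.frames
        for p in scene
    ]
    pd.DataFrame(rows, columns=["frame_id", "person_id", "x", "y", "theta"]).to_csv(
        path, index=False, float_format="%.17g"
    )
    grows = [
        {"frame_id": fid, "group_index": gi, "person_id": pid}
        for fid, scene in ff.frames
        if scene.truth is not None
        for gi, group in enumerate(scene.truth.as_lists())
        for pid in group
    ]
    if grows:
        pd.DataFrame(
            grows, columns=["frame_id", "group_index", "person_id"]
        ).to_csv(_groups_path(path), index=False)


# ---------------------------------------------------------------------------
# MATLAB benchmark layout (best effort)


def _read_mat(path: Path, degrees: bool) -> FrameFile:
    """Best-effort reader for the published benchmark .mat layout.

    Expects a cell array ``features`` with one cell per frame, each an
    (n, >=4) matrix whose columns are person id, x, y, theta (extra
    columns are ignored with a log message), and optionally a cell
    array ``GTgroups`` with per-frame cell arrays of member-id vectors.
    """
    from scipy.io import loadmat

    mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    keys = [k for k in mat if not k.startswith("__")]
    feat_key = next((k for k in ("features", "feat", "F") if k in mat), None)
    if feat_key is None:
        raise SchemaError(
            f"no 'features' cell array found in {path.name}; top-level "
            f"variables: {keys}"
        )
    unmapped = [k for k in keys if k not in (feat_key, "GTgroups", "GT")]
    if unmapped:
        logger.info("ignoring unmapped .mat variables: %s", unmapped)
    features = np.atleast_1d(mat[feat_key])
    gt_key = next((k for k in ("GTgroups", "GT") if k in mat), None)
    gt = np.atleast_1d(mat[gt_key]) if gt_key else None
    out = FrameFile(unit="cm")
    for fi, cell in enumerate(features):
        arr = np.atleast_2d(np.asarray(cell, dtype=float))
        if arr.size == 0:
            out.frames.append((fi, Scene(persons=(), truth=None)))
            continue
        if arr.shape[1] < 4:
            raise SchemaError(
                f"frame {fi}: expected >= 4 feature columns (id, x, y, theta), "
                f"got {arr.shape[1]}"
            )
        if arr.shape[1] > 4:
            logger.info(
                "frame %d: ignoring %d extra feature columns", fi, arr.shape[1] - 4
            )
        persons = tuple(
            _person_from_record(
                {
                    "id": int(row[0]),
                    "x": row[1],
                    "y": row[2],
                    "theta": math.radians(row[3]) if degrees else row[3],
                },
                degrees=False,
            )
            for row in arr[:, :4]
        )
        ids = [p.id for p in persons]
        truth = None
        if gt is not None and fi < len(gt):
            cell_gt = np.atleast_1d(gt[fi])
            # squeeze_me collapses a single-group cell to a flat vector
            # of member ids: treat that as one group, not one-per-entry
            elements = list(cell_gt)
            if cell_gt.size and all(np.isscalar(e) or np.ndim(e) == 0 for e in elements):
                group_cells = [cell_gt]
            else:
                group_cells = elements
            lists = []
            for grp in group_cells:
                members = [int(v) for v in np.atleast_1d(grp).ravel()]
                if len(members) >= 2:
                    lists.append(members)
            truth = _truth_from_lists(lists, ids)
        out.frames.append((fi, Scene(persons=persons, truth=truth, unit="cm")))
    return out


# ---------------------------------------------------------------------------
# Public API


def read_scenes(path, format: str | None = None, degrees: bool = False) -> FrameFile:
    """Read a frame file; format inferred from the suffix by default."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        return _read_json(path, degrees)
    if fmt == "csv":
        return _read_csv(path, degrees)
    if fmt == "mat":
        return _read_mat(path, degrees)
    raise ValueError(f"unsupported format {fmt!r} (expected json, csv or mat)")


def write_scenes(ff: FrameFile, path, format: str | None = None) -> None:
    """Write a frame file as canonical JSON or CSV."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        _write_json(ff, path)
    elif fmt == "csv":
        _write_csv(ff, path)
    else:
        raise ValueError(f"unsupported output format {fmt!r}")
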