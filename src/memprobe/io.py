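"""Tabular trajectory format, result serialization, and run configuration.

Trajectories travel as delimited text: a '#'-prefixed header block of
``key: value`` metadata (units are mandatory) followed by a CSV table with
columns t, x, y[, z], ux, uy, uz.  All stored quantities are SI (m, s, rad);
angles in degrees are accepted on input only with an explicit unit tag.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import LagStatistic, OrientationTrajectory, PositionTrajectory

__all__ = [
    "TrajectoryTable",
    "read_trajectory",
    "write_trajectory",
    "write_lag_statistic",
    "read_lag_statistic",
    "write_result_json",
    "config_hash",
]

_REQUIRED_HEADER = ("units",)
_COLUMNS = ["t", "x", "y", "z", "ux", "uy", "uz"]


class TrajectoryTable:
    """A trajectory table plus its header metadata.

    ``meta`` keys of note: recording_id, dt_nominal (s), R (m), center_x,
    center_y (m), rod_length (m), rod_diameter (m), temperature (K),
    eta (Pa s), octant (bool), units (must be 'SI').
    """

    def __init__(self, frame: pd.DataFrame, meta: dict):
        if "units" not in meta:
            raise ValueError("header must declare units")
        if str(meta["units"]).upper() != "SI":
            raise ValueError(f"unsupported units declaration {meta['units']!r}")
        t = frame["t"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("non-monotone time column")
        if {"ux", "uy", "uz"}.issubset(frame.columns):
            norms = np.sqrt(
                frame["ux"] ** 2 + frame["uy"] ** 2 + frame["uz"] ** 2
            ).to_numpy()
            bad = np.nonzero(np.abs(norms - 1.0) > 1e-6)[0]
            if bad.size:
                raise ValueError(
                    f"orientation not unit-norm at data row {bad[0]} "
                    f"(|u| = {norms[bad[0]]:.6f})"
                )
        self.frame = frame
        self.meta = dict(meta)

    # -- converters ---------------------------------------------------------

    def positions(self) -> PositionTrajectory:
        m = self.meta
        z = self.frame["z"].to_numpy() if "z" in self.frame.columns else None
        return PositionTrajectory(
            t=self.frame["t"].to_numpy(),
            x=self.frame["x"].to_numpy(),
            y=self.frame["y"].to_numpy(),
            z=z,
            center=(float(m.get("center_x", 0.0)), float(m.get("center_y", 0.0))),
            R=float(m["R"]) if "R" in m else None,
            meta=dict(m),
        )

    def orientations(self) -> OrientationTrajectory:
        u = self.frame[["ux", "uy", "uz"]].to_numpy()
        noise = float(self.meta.get("angular_noise_rad", np.deg2rad(1.0)))
        return OrientationTrajectory(
            t=self.frame["t"].to_numpy(),
            u=u,
            octant=bool(self.meta.get("octant", False)),
            angular_noise=noise,
            meta=dict(self.meta),
        )

    @classmethod
    def from_arrays(
        cls,
        pos: PositionTrajectory | None,
        orient: OrientationTrajectory | None,
        meta: dict | None = None,
    ) -> "TrajectoryTable":
        meta = {"units": "SI", **(meta or {})}
        cols = {}
        src = pos if pos is not None else orient
        cols["t"] = src.t
        if pos is not None:
            cols["x"], cols["y"] = pos.x, pos.y
            if pos.z is not None:
                cols["z"] = pos.z
            if pos.R is not None:
                meta.setdefault("R", pos.R)
                meta.setdefault("center_x", pos.center[0])
                meta.setdefault("center_y", pos.center[1])
        if orient is not None:
            cols["ux"], cols["uy"], cols["uz"] = orient.u.T
            meta.setdefault("octant", orient.octant)
            meta.setdefault("angular_noise_rad", orient.angular_noise)
        return cls(pd.DataFrame(cols), meta)


def _parse_header_value(v: str):
    v = v.strip()
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    if v.lower() in ("true", "false"):
        return v.lower() == "true"
    return v


def read_trajectory(path) -> TrajectoryTable:
    """Read a '#'-headered CSV trajectory; malformed rows are reported with
    their line numbers.  A vesicle file without a z column gets z
    reconstructed from the sphere geometry (flagged ``z_derived``)."""
    path = Path(path)
    meta = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = _parse_header_value(v)
    if "units" not in meta:
        raise ValueError(f"{path}: header is missing the mandatory units key")
    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed table ({err})") from err
    bad = frame.isna().any(axis=1)
    if bad.any():
        rows = (np.nonzero(bad.to_numpy())[0] + n_header + 2).tolist()
        raise ValueError(f"{path}: malformed rows at file lines {rows[:10]}")
    table = TrajectoryTable(frame, meta)
    if "z" not in frame.columns and "R" in meta and {"x", "y"}.issubset(frame.columns):
        table.frame["z"] = table.positions().reconstruct_z()
        table.meta["z_derived"] = True
        table.frame = table.frame[
            [c for c in _COLUMNS if c in table.frame.columns]
        ]
    return table


def write_trajectory(table: TrajectoryTable, path) -> None:
    """Write header + CSV with full float precision (bit-exact round trip)."""
    path = Path(path)
    cols = [c for c in _COLUMNS if c in table.frame.columns]
    with open(path, "w") as fh:
        for k, v in sorted(table.meta.items()):
            fh.write(f"# {k}: {v}\n")
        buf = _io.StringIO()
        table.frame[cols].to_csv(buf, index=False, float_format="%.17g")
        fh.write(buf.getvalue())


def write_lag_statistic(stat: LagStatistic, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind: {stat.kind}\n")
        for k, v in sorted({**stat.meta, **(meta or {})}.items()):
            if isinstance(v, (str, int, float, bool)):
                fh.write(f"# {k}: {v}\n")
        pd.DataFrame(
            {
                "lag": stat.lags,
                "value": stat.values,
                "stderr": stat.stderr,
                "n_pairs": stat.n_pairs,
            }
        ).to_csv(fh, index=False, float_format="%.17g")


def read_lag_statistic(path) -> LagStatistic:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = _parse_header_value(v)
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    return LagStatistic(
        lags=frame["lag"].to_numpy(),
        values=frame["value"].to_numpy(),
        stderr=frame["stderr"].to_numpy(),
        n_pairs=frame["n_pairs"].to_numpy(),
        kind=str(meta.pop("kind", "msd")),
        meta=meta,
    )


def _jsonify(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict (provenance stamp)."""
    payload = json.dumps(_jsonify(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_result_json(result, path, config: dict | None = None,
                      seed: int | None = None) -> None:
    """Serialize a result (dataclass or dict) with provenance metadata."""
    doc = {"result": _jsonify(result)}
    if config is not None:
        doc["config"] = _jsonify(config)
        doc["config_hash"] = config_hash(config)
    if seed is not None:
        doc["seed"] = seed
    from . import __version__

    doc["memprobe_version"] = __version__
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
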