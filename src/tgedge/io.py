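"""Plate and report I/O.

Plate files are plain CSV with a commented metadata header so that a
single file is self-contained::

    # tgedge-plate v1
    # meta.instrument: tgedge-simulator
    # well.A1.role: sample
    # well.A1.cond.amc_spike: 47
    # well.A1.cond.label: spike47_fviii1
    # pairing.spike47_fviii1: A3|A4
    time_min,well,rfu
    0,A1,50.1
    ...

Two dialects are supported: ``long`` (columns ``time_min``/``time_s``,
``well``, ``rfu``) and ``wide`` (one time column plus one column per
well).  Times given in seconds are converted to minutes on read.  Output
is deterministic (fixed column order, 12 significant digits, '.' decimal
separator) so round trips are byte-stable.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .plate import ConditionMeta, Plate, Well

__all__ = [
    "ReportDoc",
    "read_plate",
    "write_plate",
    "write_report",
    "read_report",
    "write_ground_truth",
    "read_ground_truth",
]

_MAGIC = "# tgedge-plate v1"
_FMT = "%.12g"

# entry fields written to CSV reports, in order
_PARAM_COLS = ("lag_time", "time_to_peak", "tph", "etp")


def _fmt(x: float) -> str:
    return _FMT % x


# ---------------------------------------------------------------------------
# plate files


def write_plate(plate: Plate, path: str | Path, dialect: str = "long"
                ) -> None:
    """Write a plate to CSV (``long`` or ``wide`` dialect)."""
    if dialect not in ("long", "wide"):
        raise ValueError("dialect must be 'long' or 'wide'")
    if not plate.wells:
        raise ValueError("plate has no wells; nothing to write")
    plate.validate()
    lines = [_MAGIC]
    for k in sorted(plate.meta):
        lines.append(f"# meta.{k}: {plate.meta[k]}")
    for w in plate.wells:
        lines.append(f"# well.{w.well_id}.role: {w.role}")
        for f in ConditionMeta.NUMERIC_FIELDS:
            lines.append(
                f"# well.{w.well_id}.cond.{f}: "
                f"{_fmt(getattr(w.condition, f))}"
            )
        lines.append(f"# well.{w.well_id}.cond.label: {w.condition.label}")
    for label in sorted(plate.pairing):
        ids = "|".join(plate.pairing[label])
        lines.append(f"# pairing.{label}: {ids}")
    if dialect == "long":
        lines.append("time_min,well,rfu")
        for w in plate.wells:
            for t, f in zip(w.times, w.rfu):
                lines.append(f"{_fmt(t)},{w.well_id},{_fmt(f)}")
    else:
        grid = plate.wells[0].times
        for w in plate.wells[1:]:
            if w.times.shape != grid.shape or not np.allclose(
                w.times, grid, atol=1e-12
            ):
                raise ValueError(
                    "wide dialect requires all wells on one time grid"
                )
        ids = [w.well_id for w in plate.wells]
        lines.append("time_min," + ",".join(ids))
        for i, t in enumerate(grid):
            row = [_fmt(t)] + [_fmt(w.rfu[i]) for w in plate.wells]
            lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_header(lines: list[str]):
    meta: dict = {}
    wellmeta: dict[str, dict] = {}
    pairing: dict[str, list[str]] = {}
    for ln in lines:
        body = ln[1:].strip()
        if ":" not in body:
            continue
        key, val = body.split(":", 1)
        key, val = key.strip(), val.strip()
        if key.startswith("meta."):
            meta[key[5:]] = val
        elif key.startswith("well."):
            rest = key[5:]
            wid, _, attr = rest.partition(".")
            wellmeta.setdefault(wid, {})[attr] = val
        elif key.startswith("pairing."):
            pairing[key[8:]] = [s for s in val.split("|") if s]
    return meta, wellmeta, pairing


def _condition_from(attrs: dict) -> ConditionMeta:
    kw: dict = {}
    for k, v in attrs.items():
        if not k.startswith("cond."):
            continue
        f = k[5:]
        if f == "label":
            kw[f] = v
        elif f in ConditionMeta.NUMERIC_FIELDS:
            kw[f] = float(v)
    return ConditionMeta(**kw)


def read_plate(path: str | Path, dialect: str = "auto") -> Plate:
    """Read a plate CSV written by :func:`write_plate` (or compatible).

    ``dialect`` may be ``long``, ``wide`` or ``auto`` (inferred from the
    column header).  A ``time_s`` column is converted to minutes.  Wells
    must declare a role in the header; every sample condition must have
    a calibrator pairing (explicit, or derivable from calibrator wells
    sharing the condition label).
    """
    text = Path(path).read_text()
    header = [ln for ln in text.splitlines() if ln.startswith("#")]
    body = "\n".join(ln for ln in text.splitlines()
                     if ln and not ln.startswith("#"))
    if not body:
        raise ValueError(f"{path}: no data rows")
    meta, wellmeta, pairing = _parse_header(header)
    raw_cols = body.splitlines()[0].split(",")
    dup_cols = {c for c in raw_cols if raw_cols.count(c) > 1}
    if dup_cols:
        raise ValueError(
            f"{path}: duplicated well_id in columns: {sorted(dup_cols)}"
        )
    df = pd.read_csv(_io.StringIO(body))
    cols = list(df.columns)
    time_col = cols[0]
    if time_col not in ("time_min", "time_s"):
        raise ValueError(
            f"{path}: first column must be time_min or time_s, "
            f"got {time_col!r}"
        )
    scale = 1.0 / 60.0 if time_col == "time_s" else 1.0
    if dialect == "auto":
        dialect = "long" if cols[1:3] == ["well", "rfu"] else "wide"
    wells: list[Well] = []
    if dialect == "long":
        if cols[1:3] != ["well", "rfu"]:
            raise ValueError(f"{path}: long dialect needs well,rfu columns")
        counts = df.groupby("well", sort=False).size()
        if counts.nunique() > 1:
            raise ValueError(
                f"{path}: ragged series (unequal points per well)"
            )
        for wid, grp in df.groupby("well", sort=False):
            wells.append(
                _build_well(str(wid), grp[time_col].to_numpy() * scale,
                            grp["rfu"].to_numpy(), wellmeta, path)
            )
    elif dialect == "wide":
        t = df[time_col].to_numpy() * scale
        for wid in cols[1:]:
            col = df[wid].to_numpy(dtype=float)
            if np.isnan(col).any():
                raise ValueError(f"{path}: ragged series in well {wid!r}")
            wells.append(_build_well(str(wid), t, col, wellmeta, path))
    else:
        raise ValueError("dialect must be long|wide|auto")
    if not wells:
        raise ValueError(f"{path}: no wells in file")
    ids = [w.well_id for w in wells]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValueError(f"{path}: duplicated well_id {sorted(dup)}")
    plate = Plate(wells=wells, pairing=pairing, meta=meta)
    if not pairing:
        # derive pairing from calibrator wells sharing condition labels
        for label in plate.condition_labels():
            cal = [w.well_id for w in wells
                   if w.role == "calibrator" and w.condition.label == label]
            if cal:
                plate.pairing[label] = cal
    for label in plate.condition_labels():
        if not plate.calibrator_wells(label):
            raise ValueError(
                f"{path}: condition {label!r} has no calibrator mapping"
            )
    plate.validate()
    return plate


def _build_well(wid, times, rfu, wellmeta, path) -> Well:
    attrs = wellmeta.get(wid)
    if attrs is None or "role" not in attrs:
        raise ValueError(f"{path}: well {wid!r} has no role metadata")
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, dtype=float)[order]
    if not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}: non-monotone time in well {wid!r}")
    w = Well(
        well_id=wid,
        role=attrs["role"],
        condition=_condition_from(attrs),
        times=times,
        rfu=np.asarray(rfu, dtype=float)[order],
    )
    w.validate()
    return w


# ---------------------------------------------------------------------------
# report documents


@dataclass
class ReportDoc:
    """Per-(condition, method) results with optional edge set points.

    ``entries[(condition, method)]`` is a JSON-safe dict with the TG
    parameters, a status code and any auxiliary numbers.  The grid must
    be complete: every condition x method pair present exactly once.
    """

    conditions: list[str]
    methods: list[str]
    entries: dict[tuple[str, str], dict] = field(default_factory=dict)
    set_points: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        missing = [
            (c, m)
            for c in self.conditions
            for m in self.methods
            if (c, m) not in self.entries
        ]
        if missing:
            raise ValueError(f"incomplete report grid; missing pairs: "
                             f"{missing}")
        extra = [k for k in self.entries
                 if k[0] not in self.conditions or k[1] not in self.methods]
        if extra:
            raise ValueError(f"entries outside the declared grid: {extra}")

    def to_tree(self) -> dict:
        tree: dict = {
            "meta": self.meta,
            "conditions": self.conditions,
            "methods": self.methods,
            "entries": {},
            "set_points": self.set_points,
        }
        for (c, m), e in self.entries.items():
            tree["entries"].setdefault(c, {})[m] = e
        return tree

    @classmethod
    def from_tree(cls, tree: dict) -> "ReportDoc":
        doc = cls(
            conditions=list(tree["conditions"]),
            methods=list(tree["methods"]),
            set_points=list(tree.get("set_points", [])),
            meta=dict(tree.get("meta", {})),
        )
        for c, per_method in tree.get("entries", {}).items():
            for m, e in per_method.items():
                doc.entries[(c, m)] = e
        return doc


def _json_safe(x):
    if isinstance(x, dict):
        return {k: _json_safe(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_json_safe(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        x = x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def write_report(report: ReportDoc, path: str | Path,
                 format: str = "json") -> None:
    """Serialize a report (lossless JSON, or CSV with one row per
    condition x method pair).

    In the CSV a method that refused to report (``no_curve``) appears
    with status ``failed`` and empty parameter cells.
    """
    report.validate()
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps(_json_safe(report.to_tree()), indent=2,
                       sort_keys=True) + "\n"
        )
        return
    if format != "csv":
        raise ValueError("format must be 'json' or 'csv'")
    lines = ["condition,method," + ",".join(_PARAM_COLS) + ",status,detail"]
    for c in report.conditions:
        for m in report.methods:
            e = report.entries[(c, m)]
            code = e.get("status", "ok")
            failed = code == "no_curve"
            cells = []
            for col in _PARAM_COLS:
                v = e.get(col)
                empty = failed or v is None or (
                    isinstance(v, float) and not np.isfinite(v)
                )
                cells.append("" if empty else _fmt(float(v)))
            status_out = "failed" if failed else code
            detail = str(e.get("detail", "")).replace(",", ";")
            lines.append(
                f"{c},{m}," + ",".join(cells) + f",{status_out},{detail}"
            )
    path.write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> ReportDoc:
    """Read a JSON report back into a :class:`ReportDoc`."""
    return ReportDoc.from_tree(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# ground-truth companion files


def write_ground_truth(plate: Plate, path: str | Path) -> None:
    """Export a synthetic plate's ground truth as a long CSV."""
    if not plate.truth:
        raise ValueError("plate carries no ground truth")
    cols = ("free_thrombin", "a2m_thrombin", "amidolytic", "substrate",
            "product")
    lines = ["well,time_min," + ",".join(cols)]
    for wid in sorted(plate.truth):
        g = plate.truth[wid]
        n = g.times.size
        arrays = []
        for c in cols:
            a = getattr(g, c)
            arrays.append(a if a is not None else np.full(n, np.nan))
        for i in range(n):
            row = [wid, _fmt(g.times[i])] + [_fmt(a[i]) for a in arrays]
            lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ground_truth(path: str | Path) -> dict[str, dict[str, np.ndarray]]:
    """Read a ground-truth CSV into {well: {column: array}}."""
    df = pd.read_csv(path)
    out: dict[str, dict[str, np.ndarray]] = {}
    for wid, grp in df.groupby("well", sort=False):
        out[str(wid)] = {
            c: grp[c].to_numpy(dtype=float) for c in df.columns if c != "well"
        }
    return out
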