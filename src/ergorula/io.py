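"""Delimited-text readers and writers for skeleton streams and scores.

One unambiguous CSV dialect is used everywhere: comma-separated, UTF-8,
header row required, "." decimal point, null joints encoded as empty cells.
Column layouts:

* body stream:   ``timestamp,j01_x,j01_y,j01_z,...,j16_z``
* hand stream:   ``timestamp,L00_x,L00_y,L00_z,...,R24_z``
* labels:        ``timestamp,high,middle,low`` (each row opens an interval
  that lasts until the next row's timestamp)
* expert labels: ``timestamp,segment,side,score``
* scores:        one row per fused frame, see :data:`SCORE_COLUMNS`
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .skeleton import (
    DEFAULT_BODY_REGISTRY,
    DEFAULT_HAND_REGISTRY,
    BodyJointRegistry,
    HandJointRegistry,
    Stream,
    ValidationError,
    infer_rate,
)

__all__ = [
    "FormatError",
    "read_body_stream",
    "read_hand_stream",
    "write_body_stream",
    "write_hand_stream",
    "read_labels",
    "write_labels",
    "read_expert",
    "write_scores",
    "read_scores",
    "SCORE_COLUMNS",
]


class FormatError(ValueError):
    """Raised when a file does not match the expected column layout."""


def _body_columns(registry: BodyJointRegistry) -> list[str]:
    return [f"j{tok}_{ax}" for tok in registry.tokens for ax in "xyz"]


def _hand_columns(registry: HandJointRegistry) -> list[str]:
    return [f"{lab}_{ax}" for lab in registry.columns for ax in "xyz"]


def _read_stream(path, kind: str, registry, columns: list[str],
                 nominal_rate: float | None) -> Stream:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ["timestamp", *columns] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    try:
        ts = pd.to_numeric(df["timestamp"], errors="raise").to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamp") from exc
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        raise ValidationError(f"{path}: timestamps are not strictly increasing")
    # Unparseable coordinate cells (including empties) become NaN; a joint
    # with any NaN component is treated as null as a whole.
    raw = np.column_stack(
        [pd.to_numeric(df[c], errors="coerce").to_numpy(float) for c in columns]
    )
    coords = raw.reshape(len(df), -1, 3)
    null_any = np.any(np.isnan(coords), axis=2)
    coords[null_any] = np.nan
    rate = nominal_rate if nominal_rate is not None else (
        infer_rate(ts) if len(ts) >= 2 else 1.0
    )
    return Stream(ts, coords, kind, registry, rate)


def read_body_stream(path, registry: BodyJointRegistry = DEFAULT_BODY_REGISTRY,
                     nominal_rate: float | None = None) -> Stream:
    """Read a body-joint CSV into a Stream.

    The nominal rate is inferred from the timestamps unless given.
    """
    return _read_stream(path, "body", registry, _body_columns(registry),
                        nominal_rate)


def read_hand_stream(path, registry: HandJointRegistry = DEFAULT_HAND_REGISTRY,
                     nominal_rate: float | None = None) -> Stream:
    """Read a two-hand joint CSV (25 joints per hand) into a Stream."""
    return _read_stream(path, "hand", registry, _hand_columns(registry),
                        nominal_rate)


def _write_stream(path, stream: Stream, columns: list[str]) -> None:
    flat = stream.coords.reshape(len(stream), -1)
    df = pd.DataFrame(flat, columns=columns)
    df.insert(0, "timestamp", stream.timestamps)
    df.to_csv(path, index=False, na_rep="")


def write_body_stream(path, stream: Stream) -> None:
    _write_stream(path, stream, _body_columns(stream.registry))


def write_hand_stream(path, stream: Stream) -> None:
    _write_stream(path, stream, _hand_columns(stream.registry))


# ---------------------------------------------------------------------------
# labels

def read_labels(path) -> pd.DataFrame:
    """Activity labels: timestamp,high,middle,low; rows sorted by time."""
    df = pd.read_csv(path, dtype={"high": str, "middle": str, "low": str})
    missing = [c for c in ("timestamp", "high", "middle", "low")
               if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df.sort_values("timestamp").reset_index(drop=True)


def write_labels(path, rows: Iterable[tuple]) -> None:
    df = pd.DataFrame(rows, columns=["timestamp", "high", "middle", "low"])
    df.to_csv(path, index=False)


def read_expert(path) -> pd.DataFrame:
    """Expert score rows: timestamp,segment,side,score."""
    df = pd.read_csv(path, dtype={"segment": str, "side": str})
    missing = [c for c in ("timestamp", "segment", "side", "score")
               if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# score tables

#: Output schema of the scoring stage, one row per fused frame.
SCORE_COLUMNS: tuple[str, ...] = (
    "timestamp",
    "upper_arm_left", "upper_arm_right",
    "lower_arm_left", "lower_arm_right",
    "wrist_position_left", "wrist_position_right",
    "wrist_twist_left", "wrist_twist_right",
    "neck", "trunk", "legs",
    "A_left", "A_right", "A_max", "B",
    "grand_left", "grand_right", "grand_general",
    "risk_left", "risk_right", "risk_general",
)


def write_scores(path, results: Sequence) -> pd.DataFrame:
    """Write per-frame RULA results as CSV, one row per frame.

    Rows are emitted in timestamp order regardless of input order, so the
    output is bit-stable for a given result set.  Returns the DataFrame
    written.  ``results`` must be a non-empty sequence of
    :class:`~ergorula.engine.RulaResult`.
    """
    if len(results) == 0:
        raise ValueError("write_scores requires at least one result")
    rows = [r.as_row() for r in sorted(results, key=lambda r: r.timestamp)]
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# fused frames (preprocess output / scoring input)

def write_fused(path, fused) -> None:
    """Fused-frame CSV: timestamp, body columns, hand columns, label triple."""
    if not fused:
        raise ValueError("no fused frames to write")
    body_reg = fused[0].body.registry
    hand_reg = fused[0].hands.registry
    cols = (["timestamp"] + _body_columns(body_reg) + _hand_columns(hand_reg)
            + ["high", "middle", "low"])
    rows = []
    for f in fused:
        label = f.label
        rows.append(
            [f.timestamp, *f.body.coords.ravel(), *f.hands.coords.ravel(),
             label.high if label else "", label.middle if label else "",
             label.low if label else ""]
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, na_rep="")


def read_fused(path,
               body_registry: BodyJointRegistry = DEFAULT_BODY_REGISTRY,
               hand_registry: HandJointRegistry = DEFAULT_HAND_REGISTRY):
    """Read a fused-frame CSV back into FusedFrame objects."""
    from .preprocess import FusedFrame
    from .skeleton import ActivityLabel, BodyFrame, HandFrame

    bcols = _body_columns(body_registry)
    hcols = _hand_columns(hand_registry)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ["timestamp", *bcols, *hcols] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    fused = []
    for _, row in df.iterrows():
        t = float(row["timestamp"])
        bv = pd.to_numeric(row[bcols], errors="coerce").to_numpy(float)
        hv = pd.to_numeric(row[hcols], errors="coerce").to_numpy(float)
        high = row.get("high")
        label = None
        if isinstance(high, str) and high:
            label = ActivityLabel(
                high=high,
                middle=row.get("middle") if isinstance(row.get("middle"), str) else "",
                low=row.get("low") if isinstance(row.get("low"), str) else "",
            )
        fused.append(
            FusedFrame(
                timestamp=t,
                body=BodyFrame(t, bv.reshape(-1, 3), body_registry),
                hands=HandFrame(t, hv.reshape(-1, 3), hand_registry),
                label=label,
            )
        )
    return fused
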