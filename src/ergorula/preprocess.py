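"""Rate balancing and sensor fusion.

The two sensors sample at different nominal rates (body 30 Hz, hands
64 Hz).  Before the per-frame scoring both streams are reduced to a common
20 Hz grid with Piecewise Aggregate Approximation (PAA): each coordinate
channel is cut into N equal-length segments and every segment is replaced
by its mean.  The rate-balanced streams are then joined frame-by-frame by
nearest grid timestamp, activity labels are attached by interval
containment, and frames in which any formula-required joint is null are
removed (the scoring needs every body section, so a frame with a missing
required joint cannot be scored at all).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .skeleton import (
    BODY_REQUIRED_TOKENS,
    ActivityLabel,
    BodyFrame,
    HandFrame,
    Stream,
    ValidationError,
)

__all__ = ["paa", "resample_stream", "fuse", "drop_null_rows", "FusedFrame"]

log = logging.getLogger(__name__)

#: Common grid rate after rate balancing, Hz.
DEFAULT_TARGET_RATE = 20.0


def paa(series, N: int) -> np.ndarray:
    """Piecewise Aggregate Approximation of a univariate series.

    Segment ``i`` (1-based) covers the half-open index window
    ``[ceil((i-1)*n/N), ceil(i*n/N))``, which reduces to ``n/N`` equal
    windows whenever ``N`` divides ``n``.  Nulls (NaN) are excluded from a
    segment's mean; a segment that is entirely null yields NaN.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("paa expects a univariate series")
    n = len(x)
    if n == 0:
        raise ValueError("paa of an empty series is undefined")
    if not 1 <= N <= n:
        raise ValueError(f"segment count N={N} outside [1, n={n}]")
    bounds = np.ceil(np.arange(N + 1) * n / N).astype(int)
    out = np.empty(N)
    for i in range(N):
        seg = x[bounds[i]:bounds[i + 1]]
        valid = seg[~np.isnan(seg)]
        out[i] = valid.mean() if len(valid) else np.nan
    return out


def resample_stream(stream: Stream,
                    target_rate: float = DEFAULT_TARGET_RATE) -> Stream:
    """Reduce a stream to ``target_rate`` by applying PAA per channel.

    Every joint coordinate (each joint's x, y and z) is one univariate
    series.  ``N = round(duration * target_rate)`` segments are produced and
    output timestamps are the segment-centre times of the uniform grid
    anchored at the stream start.
    """
    if stream.nominal_rate < target_rate:
        raise ValueError(
            f"cannot upsample a {stream.nominal_rate} Hz stream to "
            f"{target_rate} Hz with PAA"
        )
    n = len(stream)
    if n == 0:
        raise ValueError("cannot resample an empty stream")
    N = int(round(stream.duration * target_rate))
    N = max(1, min(N, n))
    flat = stream.coords.reshape(n, -1)
    out = np.empty((N, flat.shape[1]))
    for ch in range(flat.shape[1]):
        out[:, ch] = paa(flat[:, ch], N)
    t0 = float(stream.timestamps[0])
    ts = t0 + (np.arange(N) + 0.5) / target_rate
    return Stream(
        ts,
        out.reshape(N, stream.coords.shape[1], 3),
        stream.kind,
        stream.registry,
        target_rate,
        subject=stream.subject,
        handedness=stream.handedness,
    )


@dataclass(frozen=True)
class FusedFrame:
    """A rate-balanced, joined body+hand frame with an optional label."""

    timestamp: float
    body: BodyFrame
    hands: HandFrame
    label: ActivityLabel | None = None


def _label_at(labels: pd.DataFrame | None, t: float) -> ActivityLabel | None:
    """Label whose [timestamp, next timestamp) interval contains ``t``."""
    if labels is None or len(labels) == 0:
        return None
    ts = labels["timestamp"].to_numpy(float)
    idx = int(np.searchsorted(ts, t, side="right")) - 1
    if idx < 0:
        return None
    row = labels.iloc[idx]
    return ActivityLabel(
        high=str(row["high"]),
        middle="" if pd.isna(row["middle"]) else str(row["middle"]),
        low="" if pd.isna(row["low"]) else str(row["low"]),
    )


def fuse(body20: Stream, hand20: Stream,
         labels: pd.DataFrame | None = None,
         target_rate: float = DEFAULT_TARGET_RATE) -> list[FusedFrame]:
    """Join two rate-balanced streams by nearest grid timestamp.

    A pair is accepted when the offset is below half a grid step; unmatched
    frames on either side are dropped (the count is logged).  Labels, if
    given, are attached by interval containment.
    """
    if body20.kind != "body" or hand20.kind != "hand":
        raise ValidationError("fuse expects (body, hand) streams in order")
    if len(body20) == 0 or len(hand20) == 0:
        raise ValidationError("cannot fuse an empty stream")
    bt, ht = body20.timestamps, hand20.timestamps
    if bt[0] > ht[-1] or ht[0] > bt[-1]:
        raise ValidationError("body and hand streams cover disjoint time ranges")
    half_step = 0.5 / target_rate
    fused: list[FusedFrame] = []
    for i, t in enumerate(bt):
        j = int(np.argmin(np.abs(ht - t)))
        if abs(ht[j] - t) < half_step:
            fused.append(
                FusedFrame(
                    timestamp=float(t),
                    body=body20.frame(i),
                    hands=hand20.frame(j),
                    label=_label_at(labels, float(t)),
                )
            )
    dropped = len(bt) + len(ht) - 2 * len(fused)
    if dropped:
        log.info("fuse: %d unmatched frames dropped", dropped)
    return fused


def _required_hand_columns(registry) -> list[int]:
    return [registry.role_column(side, role)
            for side in ("left", "right") for role in registry.roles]


def drop_null_rows(fused: Sequence[FusedFrame]) -> tuple[list[FusedFrame], int]:
    """Remove fused frames in which any formula-required joint is null.

    Only joints referenced by a scoring formula matter; a null in e.g. a
    knee joint does not discard the frame.  Returns (kept frames, number
    removed) and warns when everything was removed.
    """
    kept: list[FusedFrame] = []
    for f in fused:
        body_ok = all(
            f.body.joint(tok) is not None for tok in BODY_REQUIRED_TOKENS
        )
        hand_cols = _required_hand_columns(f.hands.registry)
        hand_ok = not np.any(np.isnan(f.hands.coords[hand_cols]))
        if body_ok and hand_ok:
            kept.append(f)
    removed = len(fused) - len(kept)
    if fused and not kept:
        log.warning("drop_null_rows: all %d frames removed", len(fused))
    elif removed:
        log.info("drop_null_rows: %d of %d frames removed", removed, len(fused))
    return kept, removed
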