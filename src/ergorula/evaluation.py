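"""Agreement with expert labels and across-subject hypothesis tests.

The system's per-frame scores are compared against an expert's sparse
labels (every k-th fused frame, default k=10, i.e. one label per 0.5 s at
20 Hz).  Agreement between one expert score ``es`` and one system score
``ss`` is the bounded similarity

    numSim(es, ss) = 1 - |es - ss| / (es + ss)        in (0, 1],

and a score series is summarised by the mean similarity ``tsim`` over
aligned pairs.  Reports stratify by (segment, side, high-level activity).

Across-subject heterogeneity is tested with a one-way ANOVA over grand
scores grouped by subject, followed by all pairwise two-sample t-tests
(Student's equal-variance by default, Welch optional), flagged at
alpha = 0.05.  No multiple-testing correction is applied by default; a
Bonferroni/Holm option is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "activity_series",
    "num_sim",
    "tsim",
    "similarity_report",
    "SubjectComparison",
    "subject_comparison",
]

log = logging.getLogger(__name__)

#: expert labelling stride in fused frames (one label per 0.5 s at 20 Hz).
DEFAULT_STRIDE = 10

#: segment/side pairs a report covers, mapped to score-table columns.
REPORT_COLUMNS: dict[tuple[str, str], str] = {
    ("upper_arm", "left"): "upper_arm_left",
    ("upper_arm", "right"): "upper_arm_right",
    ("lower_arm", "left"): "lower_arm_left",
    ("lower_arm", "right"): "lower_arm_right",
    ("wrist_position", "left"): "wrist_position_left",
    ("wrist_position", "right"): "wrist_position_right",
    ("wrist_twist", "left"): "wrist_twist_left",
    ("wrist_twist", "right"): "wrist_twist_right",
    ("neck", "center"): "neck",
    ("trunk", "center"): "trunk",
    ("legs", "center"): "legs",
    ("A", "left"): "A_left",
    ("A", "right"): "A_right",
    ("A", "max"): "A_max",
    ("B", "center"): "B",
    ("grand", "left"): "grand_left",
    ("grand", "right"): "grand_right",
    ("grand", "general"): "grand_general",
}


def activity_series(scores: pd.DataFrame, labels: pd.DataFrame) -> pd.Series:
    """High-level activity of each scored frame, by label-interval
    containment (each label row spans until the next row's timestamp)."""
    lts = labels["timestamp"].to_numpy(float)
    sts = scores["timestamp"].to_numpy(float)
    idx = np.clip(np.searchsorted(lts, sts, side="right") - 1, 0,
                  len(lts) - 1)
    return pd.Series(labels["high"].to_numpy()[idx], index=scores.index)


def num_sim(es: float, ss: float) -> float:
    """Similarity ``1 - |es - ss| / (es + ss)`` between two scores >= 1."""
    if es < 1 or ss < 1:
        raise ValueError("scores must be >= 1 for the similarity measure")
    return 1.0 - abs(es - ss) / (es + ss)


def tsim(es, ss) -> float:
    """Mean similarity over two aligned, equal-length score series."""
    es = np.asarray(es, dtype=float)
    ss = np.asarray(ss, dtype=float)
    if es.shape != ss.shape or es.ndim != 1:
        raise ValueError("tsim needs two aligned 1-D score series")
    if len(es) == 0:
        raise ValueError("tsim of empty series is undefined")
    if np.any(es < 1) or np.any(ss < 1):
        raise ValueError("scores must be >= 1 for the similarity measure")
    return float(np.mean(1.0 - np.abs(es - ss) / (es + ss)))


class AlignmentError(ValueError):
    """Expert rows that match no scored frame."""


def similarity_report(expert: pd.DataFrame, scores: pd.DataFrame,
                      activities: pd.Series | None = None,
                      tolerance: float = 1e-6) -> pd.DataFrame:
    """Mean similarity per (segment, side, activity) stratum.

    ``expert`` is long-form (timestamp, segment, side, score); ``scores``
    is the wide per-frame score table; ``activities`` optionally maps score
    rows to high-level activity names (index-aligned with ``scores``).
    Strata with no labelled rows are simply absent, never fabricated.
    Raises :class:`AlignmentError` when an expert timestamp matches no
    scored frame within ``tolerance`` seconds.
    """
    ts = scores["timestamp"].to_numpy(float)
    ets = expert["timestamp"].to_numpy(float)
    pos = np.searchsorted(ts, ets)
    pos = np.clip(pos, 0, len(ts) - 1)
    left = np.clip(pos - 1, 0, len(ts) - 1)
    pick = np.where(
        np.abs(ts[left] - ets) <= np.abs(ts[pos] - ets), left, pos
    )
    bad = np.abs(ts[pick] - ets) > tolerance
    if np.any(bad):
        raise AlignmentError(
            f"{int(bad.sum())} expert rows match no scored frame; first "
            f"offending timestamp {ets[bad][0]!r}"
        )
    rows = []
    for (_, erow), k in zip(expert.iterrows(), pick):
        key = (str(erow["segment"]), str(erow["side"]))
        col = REPORT_COLUMNS.get(key)
        if col is None:
            log.warning("similarity_report: unknown stratum %r skipped", key)
            continue
        system = float(scores.iloc[k][col])
        activity = (
            str(activities.iloc[k]) if activities is not None else "all"
        )
        rows.append(
            {"segment": key[0], "side": key[1], "activity": activity,
             "similarity": num_sim(float(erow["score"]), system)}
        )
    if not rows:
        raise AlignmentError("no comparable expert rows")
    df = pd.DataFrame(rows)
    return (
        df.groupby(["segment", "side", "activity"])["similarity"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "tsim", "count": "n"})
        .reset_index()
    )


@dataclass(frozen=True)
class SubjectComparison:
    """One-way ANOVA plus the pairwise t-test matrix over subjects."""

    subjects: tuple[str, ...]
    anova_F: float
    anova_p: float
    pairwise_p: pd.DataFrame      # symmetric, unit diagonal
    significant: pd.DataFrame     # boolean at the chosen alpha
    alpha: float = 0.05
    excluded: tuple[str, ...] = field(default_factory=tuple)


def subject_comparison(per_subject: dict[str, np.ndarray],
                       alpha: float = 0.05,
                       equal_var: bool = True,
                       correction: str | None = None) -> SubjectComparison:
    """Test whether subjects share a common mean grand score.

    ``per_subject`` maps subject id to that subject's per-frame grand-score
    sample.  Subjects with fewer than 2 frames are excluded with a warning.
    ``correction`` may be "bonferroni" or "holm" (off by default, matching
    the plain pairwise presentation).
    """
    usable, excluded = {}, []
    for sid, sample in per_subject.items():
        sample = np.asarray(sample, dtype=float)
        if len(sample) < 2:
            log.warning("subject %s excluded (n=%d < 2)", sid, len(sample))
            excluded.append(sid)
        else:
            usable[sid] = sample
    ids = tuple(usable)
    if len(ids) < 2:
        raise ValueError("subject comparison needs at least 2 usable subjects")
    F, p = stats.f_oneway(*usable.values())
    s = len(ids)
    pmat = np.ones((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            if np.array_equal(usable[ids[i]], usable[ids[j]]):
                pij = 1.0  # identical samples: no evidence of difference
            else:
                pij = float(
                    stats.ttest_ind(
                        usable[ids[i]], usable[ids[j]], equal_var=equal_var
                    ).pvalue
                )
            pmat[i, j] = pmat[j, i] = pij
    if correction:
        iu = np.triu_indices(s, k=1)
        raw = pmat[iu]
        if correction == "bonferroni":
            adj = np.minimum(raw * len(raw), 1.0)
        elif correction == "holm":
            order = np.argsort(raw)
            adj = np.empty_like(raw)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, raw[idx] * (len(raw) - rank))
                adj[idx] = min(running, 1.0)
        else:
            raise ValueError(f"unknown correction {correction!r}")
        pmat[iu] = adj
        pmat.T[iu] = adj
    pdf = pd.DataFrame(pmat, index=ids, columns=ids)
    return SubjectComparison(
        subjects=ids,
        anova_F=float(F),
        anova_p=float(p),
        pairwise_p=pdf,
        significant=(pdf < alpha) & ~np.eye(s, dtype=bool),
        alpha=alpha,
        excluded=tuple(excluded),
    )
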