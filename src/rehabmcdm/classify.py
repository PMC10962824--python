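"""Five-class recovery classification and class-boundary calibration.

Aggregate recovery scores in [0, 1] are mapped to five ordered impairment
classes following the ICF qualifier idea (I complete impairment ... V no
impairment).  Class boundaries can come from two calibrations:

* ``expert``  -- derived from the expert panel's per-patient class labels:
  the span of each labelled class, after rejecting boundary-distorting
  labels whose recomputed majority vote disagrees with the recorded class;
* ``kmeans``  -- derived from 1-D K-Means (k-means++ seeding, best SSE over
  restarts) on the corrected value set: all aggregate scores from both
  assessments plus an added minimum of 0.01, so the score axis is anchored
  near 0 as well as at the healthy reference's 1.

Raw per-class intervals leave gaps; internal gaps are closed by splitting
them at the midpoint (gap halving) and rounding, while degenerate extreme
clusters (the added 0.01, the healthy 1.0s) act as anchors whose neighbour
boundary is closed one tick away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, floor

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

ICF_LABELS = (
    "I Complete impairment",
    "II Severe impairment",
    "III Moderate impairment",
    "IV Mild impairment",
    "V No impairment",
)

_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}
_FROM_ROMAN = {v: k for k, v in _ROMAN.items()}


def to_roman(cls: int) -> str:
    return _ROMAN[int(cls)]


def from_roman(label: str) -> int:
    key = str(label).strip().upper().replace(" CLASS", "").strip()
    return _FROM_ROMAN[key]


class ClassModelError(ValueError):
    pass


@dataclass(frozen=True)
class ClassModel:
    """Ordered, non-overlapping class intervals on the score axis."""

    intervals: tuple[tuple[float, float], ...]
    provenance: str = "expert"
    labels: tuple[str, ...] = ICF_LABELS
    rounding: int = 3

    def __post_init__(self):
        ivals = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        object.__setattr__(self, "intervals", ivals)
        for lo, hi in ivals:
            if hi < lo:
                raise ClassModelError(f"interval [{lo}, {hi}] is inverted")
        for (lo1, hi1), (lo2, hi2) in zip(ivals, ivals[1:]):
            if lo2 <= hi1:
                raise ClassModelError(
                    f"intervals overlap or touch: [{lo1}, {hi1}] then [{lo2}, {hi2}]"
                )

    @property
    def k(self) -> int:
        return len(self.intervals)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "intervals": [list(iv) for iv in self.intervals],
            "labels": list(self.labels),
            "rounding": self.rounding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassModel":
        return cls(
            intervals=tuple(tuple(iv) for iv in d["intervals"]),
            provenance=d.get("provenance", "expert"),
            labels=tuple(d.get("labels", ICF_LABELS)),
            rounding=int(d.get("rounding", 3)),
        )


@dataclass(frozen=True)
class ClusterModel:
    """A 1-D K-Means solution with clusters ordered by centroid."""

    values: np.ndarray
    centroids: np.ndarray  # ascending
    labels: np.ndarray  # 0-based, aligned with values, ascending by centroid
    sse: float

    def members(self, i: int) -> np.ndarray:
        return np.sort(self.values[self.labels == i])


@dataclass(frozen=True)
class ExpertVotes:
    """Per-patient, per-assessment class votes of the expert panel.

    ``frame`` columns: ``patient``, ``assessment``, ``reference`` (the
    recorded consensus class, int 1..5) and one ``expert_<i>`` column per
    expert with individual votes.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        req = {"patient", "assessment", "reference"}
        missing = req - set(self.frame.columns)
        if missing:
            raise ValueError(f"votes table missing columns {sorted(missing)}")
        vote_cols = self.vote_columns()
        for col in vote_cols + ["reference"]:
            bad = ~self.frame[col].isin(range(1, 6))
            if bad.any():
                raise ValueError(f"column {col}: classes must be in 1..5")

    def vote_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("expert_")]


@dataclass(frozen=True)
class ConsensusResult:
    consensus: pd.Series  # index (patient, assessment) -> class
    discrepancies: pd.DataFrame  # rows where recorded reference != majority


@dataclass(frozen=True)
class OutlierReport:
    kept: pd.DataFrame  # columns patient, assessment, score, class
    rejected: pd.DataFrame


@dataclass(frozen=True)
class AgreementReport:
    agreement: float
    boundary_deltas: np.ndarray  # (k, 2) model_a - model_b
    crosstab: pd.DataFrame
    mismatches: pd.DataFrame


# ---------------------------------------------------------------------------
# class assignment


def assign_class(score: float, model: ClassModel) -> int:
    """Class (1..k) whose interval contains the score.

    Intervals are closed; a score falling in the rounding gap between two
    intervals belongs to the upper class.
    """
    score = float(score)
    lo0 = model.intervals[0][0]
    hi_last = model.intervals[-1][1]
    eps = 1e-12
    if score < lo0 - eps or score > hi_last + eps:
        raise ValueError(
            f"score {score} outside the admissible range [{lo0}, {hi_last}]"
        )
    for i, (_, hi) in enumerate(model.intervals):
        if score <= hi:
            return i + 1
    return model.k


def class_distribution(scores, model: ClassModel) -> np.ndarray:
    """Counts per class for a list of scores (sums to len(scores))."""
    counts = np.zeros(model.k, dtype=int)
    for s in scores:
        counts[assign_class(s, model) - 1] += 1
    return counts


# ---------------------------------------------------------------------------
# K-Means calibration


def kmeans_1d(values, k: int, n_restarts: int = 50, seed: int = 0) -> ClusterModel:
    """Best-of-restarts Lloyd K-Means with k-means++ seeding on 1-D data.

    Deterministic given ``seed``.  On one-dimensional data every cluster of
    a converged solution is a contiguous interval of the sorted values,
    which is asserted on the returned model.
    """
    values = np.asarray(values, dtype=float).ravel()
    distinct = np.unique(values)
    if k > distinct.size:
        raise ValueError(
            f"k={k} exceeds the number of distinct values ({distinct.size})"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed).fit(values.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[km.labels_]
    # contiguity check: sorted values must have non-decreasing cluster index
    sorted_labels = labels[np.argsort(values, kind="stable")]
    if (np.diff(sorted_labels) < 0).any():
        raise AssertionError("1-D K-Means produced non-contiguous clusters")
    return ClusterModel(values=values, centroids=centers[order], labels=labels,
                        sse=float(km.inertia_))


def clusters_to_intervals(cm: ClusterModel) -> list[tuple[float, float]]:
    """Per cluster (ascending centroid) the raw [min member, max member]."""
    return [
        (float(cm.members(i).min()), float(cm.members(i).max()))
        for i in range(len(cm.centroids))
    ]


def _round_down(x: float, decimals: int) -> float:
    return floor(x * 10**decimals + 1e-9) / 10**decimals


def _round_up(x: float, decimals: int) -> float:
    return ceil(x * 10**decimals - 1e-9) / 10**decimals


def adjust_intervals(
    raw,
    rounding: int = 3,
    anchor_decimals: int = 4,
    provenance: str = "kmeans",
    labels: tuple[str, ...] | None = None,
) -> ClassModel:
    """Close the gaps between raw class intervals into a contiguous model.

    Internal gaps are split at their midpoint; the lower class's upper bound
    is rounded down and the upper class's lower bound rounded up to
    ``rounding`` decimals (when both round to the same tick the lower bound
    wins and the upper bound of the class below backs off one tick), so that
    intervals never overlap and every raw member stays inside its own class.

    A zero-width extreme interval (a degenerate anchor cluster such as the
    added minimum 0.01 or the healthy 1.0s) does not take part in halving:
    its neighbour's raw bound is kept and the anchor-side boundary is closed
    one tick (10^-anchor_decimals) away from it.  The top class always ends
    at 1, the admissible maximum of a normalized score.
    """
    raw = [(float(lo), float(hi)) for lo, hi in raw]
    for (lo1, hi1), (lo2, hi2) in zip(raw, raw[1:]):
        if lo2 <= hi1:
            raise ClassModelError(
                f"raw intervals must be ordered and disjoint, got [{lo1}, {hi1}] "
                f"then [{lo2}, {hi2}]"
            )
    k = len(raw)
    los = [iv[0] for iv in raw]
    his = [iv[1] for iv in raw]
    tick = 10.0 ** -rounding
    atick = 10.0 ** -anchor_decimals
    for c in range(k - 1):
        gap = los[c + 1] - his[c]
        if gap <= tick:  # already contiguous at this rounding
            continue
        first_anchor = c == 0 and raw[0][0] == raw[0][1]
        last_anchor = c + 1 == k - 1 and raw[-1][0] == raw[-1][1]
        if first_anchor:
            his[c] = los[c + 1] - atick
        elif last_anchor:
            los[c + 1] = his[c] + atick
        else:
            mid = (his[c] + los[c + 1]) / 2.0
            new_hi = max(_round_down(mid, rounding), raw[c][1])
            new_lo = min(_round_up(mid, rounding), raw[c + 1][0])
            if new_hi >= new_lo:
                new_hi = new_lo - tick
            his[c], los[c + 1] = new_hi, new_lo
    his[-1] = max(his[-1], 1.0)
    model_labels = labels or (ICF_LABELS if k == 5 else tuple(f"class {i+1}" for i in range(k)))
    return ClassModel(
        intervals=tuple(zip(los, his)),
        provenance=provenance,
        labels=model_labels,
        rounding=rounding,
    )


def corrected_value_set(scores_I, scores_II, extra_min: float = 0.01) -> np.ndarray:
    """All aggregate scores of both assessments plus an added minimum.

    The two assessment vectors (each including the healthy reference's 1.0)
    are concatenated as a multiset and the constant ``extra_min`` is
    appended: the score scale has an attainable maximum of 1, so the
    calibration also anchors a near-zero minimum.
    """
    return np.concatenate(
        [np.asarray(scores_I, float).ravel(),
         np.asarray(scores_II, float).ravel(),
         [float(extra_min)]]
    )


def kmeans_class_model(
    values, k: int = 5, n_restarts: int = 50, seed: int = 0, rounding: int = 3
) -> ClassModel:
    """Calibrate class boundaries by clustering the corrected value set."""
    cm = kmeans_1d(values, k, n_restarts=n_restarts, seed=seed)
    return adjust_intervals(clusters_to_intervals(cm), rounding=rounding,
                            provenance="kmeans")


# ---------------------------------------------------------------------------
# expert-label calibration


def consensus_class(votes: ExpertVotes) -> ConsensusResult:
    """Majority vote per patient and assessment; ties go to the worse class.

    Rows where the recorded reference class disagrees with the recomputed
    majority are reported, never silently overridden.
    """
    vote_cols = votes.vote_columns()
    if not vote_cols:
        raise ValueError("votes table has no expert_<i> columns")

    def majority(row) -> int:
        counts = row[vote_cols].value_counts()
        top = counts[counts == counts.max()]
        return int(min(top.index))  # lower class = worse impairment

    f = votes.frame
    maj = f.apply(majority, axis=1)
    consensus = pd.Series(
        maj.values, index=pd.MultiIndex.from_frame(f[["patient", "assessment"]])
    )
    disagree = f[maj != f["reference"]].copy()
    disagree["majority"] = maj[maj != f["reference"]]
    return ConsensusResult(consensus=consensus, discrepancies=disagree)


def reject_outliers(votes: ExpertVotes, scores: pd.DataFrame) -> OutlierReport:
    """Drop boundary-distorting disputed labels before boundary derivation.

    ``scores`` is tidy with columns ``patient``, ``assessment``, ``score``.
    A score is rejected when (a) the recomputed majority vote disagrees with
    the recorded reference class -- the label is disputed -- and (b) the
    score lies strictly outside the span of the other members of its
    recorded class, i.e. keeping the disputed label would move a class
    boundary.  On concordant (monotone) labels nothing is rejected.
    """
    res = consensus_class(votes)
    merged = scores.merge(
        votes.frame[["patient", "assessment", "reference"]],
        on=["patient", "assessment"], how="inner",
    ).rename(columns={"reference": "class"})
    maj = res.consensus
    flags = []
    for idx, row in merged.iterrows():
        key = (row["patient"], row["assessment"])
        disputed = key in maj.index and maj.loc[key] != row["class"]
        if not disputed:
            flags.append(False)
            continue
        others = merged[(merged["class"] == row["class"]) & (merged.index != idx)]["score"]
        outside = len(others) > 0 and (
            row["score"] < others.min() or row["score"] > others.max()
        )
        flags.append(bool(outside))
    flags = np.array(flags, dtype=bool)
    return OutlierReport(
        kept=merged[~flags].reset_index(drop=True),
        rejected=merged[flags].reset_index(drop=True),
    )


def _resolve_overlaps(raw, delta: float = 1e-6):
    """Make class spans disjoint by splitting each overlap at its midpoint.

    Labelled spans derived from noisy votes can overlap; the boundary
    between two overlapping neighbours is placed halfway between the lower
    class's max and the upper class's min (the same midpoint rule that
    closes gaps, applied with a negative gap)."""
    resolved: list[tuple[float, float]] = []
    for lo, hi in raw:
        if resolved and lo <= resolved[-1][1]:
            m = (resolved[-1][1] + lo) / 2.0
            m = max(m, resolved[-1][0] + delta)
            resolved[-1] = (resolved[-1][0], m - delta)
            lo = m + delta
        resolved.append((lo, max(hi, lo)))
    return resolved


def expert_class_model(
    votes: ExpertVotes,
    scores: pd.DataFrame,
    healthy_scores=(1.0, 1.0),
    anchor_low: float = 0.01,
    k: int = 5,
    rounding: int = 3,
    classes=None,
) -> ClassModel:
    """Derive class boundaries from expert labels.

    Labelled patient scores (both assessments, outliers rejected) span
    classes; the healthy reference's scores belong to the best class and
    the added minimum ``anchor_low`` is the sole member of the worst,
    mirroring the corrected value set used by the K-Means calibration.

    ``classes`` optionally restricts the model to an ordered subset of the
    1..5 class ids (e.g. when a cohort simply contains no class-IV
    patients); stray labels snap to the nearest retained class, ties to
    the worse one.
    """
    report = reject_outliers(votes, scores)
    class_ids = sorted(int(c) for c in classes) if classes is not None else list(range(1, k + 1))
    arr = np.array(class_ids)
    members: dict[int, list[float]] = {c: [] for c in class_ids}
    for _, row in report.kept.iterrows():
        nearest = int(arr[np.argmin(np.abs(arr - int(row["class"])))])
        members[nearest].append(float(row["score"]))
    members[class_ids[-1]].extend(float(s) for s in healthy_scores)
    members[class_ids[0]].append(float(anchor_low))
    empty = [c for c, vals in members.items() if not vals]
    if empty:
        raise ClassModelError(f"no labelled scores for classes {empty}")
    raw = _resolve_overlaps(
        [(min(members[c]), max(members[c])) for c in class_ids]
    )
    labels = ICF_LABELS if class_ids == [1, 2, 3, 4, 5] else tuple(
        f"class {c}" for c in class_ids
    )
    return adjust_intervals(raw, rounding=rounding, provenance="expert", labels=labels)


# ---------------------------------------------------------------------------
# model comparison


def compare_models(a: ClassModel, b: ClassModel, scores) -> AgreementReport:
    """Boundary deltas and classification agreement of two class models."""
    if a.k != b.k:
        raise ValueError("models must have the same number of classes")
    deltas = np.array(
        [[la - lb, ha - hb] for (la, ha), (lb, hb) in zip(a.intervals, b.intervals)]
    )
    rows = []
    for s in scores:
        ca, cb = assign_class(s, a), assign_class(s, b)
        rows.append({"score": float(s), "class_a": ca, "class_b": cb})
    df = pd.DataFrame(rows)
    agreement = float((df["class_a"] == df["class_b"]).mean()) if len(df) else 1.0
    crosstab = pd.crosstab(df["class_a"], df["class_b"]) if len(df) else pd.DataFrame()
    return AgreementReport(
        agreement=agreement,
        boundary_deltas=deltas,
        crosstab=crosstab,
        mismatches=df[df["class_a"] != df["class_b"]].reset_index(drop=True),
    )
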