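"""SWARA (Step-wise Weight Assessment Ratio Analysis) criteria weighting.

Experts first rank the criteria by importance, then state, for each pair of
rank-neighbours, how much more important the higher-ranked criterion is
(a value s in [0, 1]).  The weight recursion is

    k_1 = 1,            k_j = s_j + 1        (j >= 2)
    q_1 = 1,            q_j = q_{j-1} / k_j  (j >= 2)
    w_j = q_j / sum_i q_i

so weights decay along the ranking at a rate set by the stated comparative
importances.  Final sub-criterion weights are the criterion weight times the
sub-criterion's percent share.

Note the ranking is by the experts' direct-importance priors, not by
criterion label order; with the packaged defaults c7 outranks c6, and the
pair values attach to rank positions, not to label indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hierarchy import CriteriaHierarchy


class PanelError(ValueError):
    """Invalid expert panel input."""


@dataclass(frozen=True)
class ExpertPanel:
    """Adjacent-pair comparative-importance statements of an expert panel.

    ``values`` has one row per expert and one column per rank-position pair:
    column p (0-based) holds each expert's comparative importance between the
    criteria at rank positions p+1 and p+2.  All entries lie in [0, 1].
    """

    values: np.ndarray
    expert_ids: tuple[str, ...] = ()

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise PanelError("panel must be a non-empty 2-D array (experts x pairs)")
        if np.isnan(arr).any():
            raise PanelError("panel contains missing values")
        if (arr < 0).any() or (arr > 1).any():
            bad = arr[(arr < 0) | (arr > 1)]
            raise PanelError(f"pair values must lie in [0, 1]; offending values: {bad.tolist()}")
        object.__setattr__(self, "values", arr)
        if not self.expert_ids:
            object.__setattr__(
                self, "expert_ids", tuple(str(i + 1) for i in range(arr.shape[0]))
            )

    @property
    def n_experts(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class WeightSet:
    """SWARA weights along a criterion ranking.

    All vectors are aligned with ``ranking`` (descending importance);
    ``s[0]`` is 0 by convention (the top criterion is compared to nothing).
    ``sub_weights`` maps sub-criterion id -> final weight and is empty until
    :func:`propagate_sub_weights` is applied.
    """

    ranking: tuple[str, ...]
    s: np.ndarray
    k: np.ndarray
    q: np.ndarray
    w: np.ndarray
    sub_weights: dict[str, float] = field(default_factory=dict)

    def weight(self, cid: str) -> float:
        return float(self.w[self.ranking.index(cid)])

    def as_frame(self) -> pd.DataFrame:
        """Weight report, one row per criterion in ranking order."""
        return pd.DataFrame(
            {"criterion": self.ranking, "s": self.s, "k": self.k, "q": self.q, "w": self.w}
        )

    def sub_weight_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sub_criterion": list(self.sub_weights), "weight": list(self.sub_weights.values())}
        )


def rank_by_direct_importance(hierarchy: CriteriaHierarchy) -> tuple[str, ...]:
    """Criterion ids sorted by descending expert prior importance.

    Ties break deterministically by ascending criterion id.
    """
    return tuple(
        c.id
        for c in sorted(hierarchy.criteria, key=lambda c: (-c.direct_importance, c.id))
    )


def average_pair_values(panel: ExpertPanel) -> np.ndarray:
    """Arithmetic mean over experts per rank-position pair (s-vector).

    Entry p is the averaged comparative importance between the criteria at
    rank positions p+1 and p+2.
    """
    return panel.values.mean(axis=0)


def swara_weights(s: np.ndarray, ranking: tuple[str, ...] | list[str]) -> WeightSet:
    """Run the SWARA recursion for an s-vector along a ranking.

    ``s`` holds one averaged pair value per rank position >= 2 (length
    ``len(ranking) - 1``); the value at index p lands on the criterion at
    rank position p+2.
    """
    ranking = tuple(ranking)
    s = np.asarray(s, dtype=float)
    n = len(ranking)
    if s.shape != (n - 1,):
        raise ValueError(f"expected {n - 1} pair values for {n} criteria, got {s.shape}")
    if n == 0:
        raise ValueError("empty ranking")
    if ((s < 0) | (s > 1)).any():
        raise ValueError(f"s values must lie in [0, 1], got {s.tolist()}")
    s_full = np.concatenate([[0.0], s])
    k = np.concatenate([[1.0], s + 1.0])
    q = np.empty(n)
    q[0] = 1.0
    for j in range(1, n):
        q[j] = q[j - 1] / k[j]
    w = q / q.sum()
    return WeightSet(ranking=ranking, s=s_full, k=k, q=q, w=w)


def propagate_sub_weights(ws: WeightSet, hierarchy: CriteriaHierarchy) -> WeightSet:
    """Attach final sub-criterion weights: w(criterion) x percent share."""
    sub_weights: dict[str, float] = {}
    for c in hierarchy.criteria:
        wc = ws.weight(c.id)
        for sub in c.effective_subs():
            sub_weights[sub.id] = wc * sub.percent_share
    return replace(ws, sub_weights=sub_weights)


def compute_weights(hierarchy: CriteriaHierarchy, panel: ExpertPanel) -> WeightSet:
    """Full chain: rank -> average pair values -> recursion -> sub-weights."""
    ranking = rank_by_direct_importance(hierarchy)
    s = average_pair_values(panel)
    return propagate_sub_weights(swara_weights(s, ranking), hierarchy)
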