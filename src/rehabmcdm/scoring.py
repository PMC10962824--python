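"""Situation vectors, compromise min-max normalization and weighted aggregation.

Each patient (alternative) is described at one assessment time by a vector
of ordinal sub-criterion scores x_ij.  Scores are normalized to [0, 1] with
the compromise min-max equations

    benefit rows:  r = (x - min) / (max - min)
    cost rows:     r = (max - x) / (max - min)

so that 1 is always the healthy end of every row, and aggregated with the
weighted-sum (simple additive weighting) formula  WAM = sum_j w_j r_ij.

The min/max pool defaults to the theoretical scale bounds of each
sub-criterion, which makes scores comparable across assessments and pins
the healthy-reference alternative at exactly 1; an empirical pool (min/max
over observed alternatives) is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import BENEFIT, CriteriaHierarchy
from .swara import WeightSet

log = logging.getLogger(__name__)

HEALTHY = "healthy"

THEORETICAL = "theoretical"
EMPIRICAL = "empirical"


class ScoreError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreMatrix:
    """Raw ordinal scores: rows = sub-criteria, columns = alternatives."""

    assessment_id: str
    data: pd.DataFrame

    def validate(self, hierarchy: CriteriaHierarchy) -> None:
        problems = []
        expected = hierarchy.sub_ids()
        missing = [sid for sid in expected if sid not in self.data.index]
        if missing:
            problems.append(f"missing sub-criterion rows: {missing}")
        extra = [sid for sid in self.data.index if sid not in expected]
        if extra:
            problems.append(f"unknown sub-criterion rows: {extra}")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            problems.append(f"missing scores for alternatives: {bad}")
        for _, sub in hierarchy.iter_subs():
            if sub.id not in self.data.index:
                continue
            lo, hi = sub.scale_bounds()
            row = self.data.loc[sub.id]
            bad = row[(row < lo) | (row > hi)]
            if len(bad):
                problems.append(
                    f"sub-criterion {sub.id}: scores outside scale [{lo}, {hi}] "
                    f"for alternatives {bad.index.tolist()}"
                )
        if HEALTHY in self.data.columns and not problems:
            for _, sub in hierarchy.iter_subs():
                if self.data.loc[sub.id, HEALTHY] != sub.best_level():
                    problems.append(
                        f"healthy reference must hold the best level on {sub.id}"
                    )
        if problems:
            raise ScoreError(f"assessment {self.assessment_id}: " + "; ".join(problems))

    @property
    def alternatives(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class NormalizedMatrix:
    """Normalized scores r_ij in [0, 1], same shape as the raw matrix."""

    assessment_id: str
    data: pd.DataFrame
    group_of: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class AggregateScores:
    """Per-alternative aggregate recovery scores for one or more assessments.

    ``frame`` is tidy: one row per (alternative, assessment) with columns
    ``wam_score`` (the weighted aggregate used for classification),
    ``table7_view`` (unweighted mean of the criterion-group means, reported
    for comparison) and one mean-normalized-value column per criterion group.
    """

    frame: pd.DataFrame

    def wam(self, assessment_id: str | None = None) -> pd.Series:
        f = self.frame
        if assessment_id is not None:
            f = f[f["assessment"] == assessment_id]
        return f.set_index("alternative")["wam_score"]

    def assessments(self) -> list[str]:
        return list(dict.fromkeys(self.frame["assessment"]))


def healthy_reference_column(hierarchy: CriteriaHierarchy) -> pd.Series:
    """Best possible level on every sub-criterion (scores exactly 1)."""
    return pd.Series(
        {sub.id: sub.best_level() for _, sub in hierarchy.iter_subs()}, name=HEALTHY
    )


def normalize(
    matrix: ScoreMatrix,
    hierarchy: CriteriaHierarchy,
    pool: str = THEORETICAL,
    pool_matrices: list[ScoreMatrix] | None = None,
) -> NormalizedMatrix:
    """Apply the compromise min-max equations row by row.

    ``pool`` selects where per-row min and max come from: the theoretical
    scale bounds (default) or the empirically observed values across this
    matrix and any ``pool_matrices`` (e.g. the other assessment, so both
    assessments share one scale).  A row with zero spread normalizes to 1
    for every alternative -- a constant criterion should not penalize
    anyone -- and is logged as a warning.
    """
    if pool not in (THEORETICAL, EMPIRICAL):
        raise ValueError(f"unknown normalization pool {pool!r}")
    matrix.validate(hierarchy)
    out = pd.DataFrame(index=matrix.data.index, columns=matrix.data.columns, dtype=float)
    group_of = {}
    for crit, sub in hierarchy.iter_subs():
        group_of[sub.id] = crit.group_id
        row = matrix.data.loc[sub.id].astype(float)
        if pool == THEORETICAL:
            lo, hi = sub.scale_bounds()
        else:
            pooled = [row]
            for m in pool_matrices or []:
                pooled.append(m.data.loc[sub.id].astype(float))
            allvals = pd.concat(pooled)
            lo, hi = float(allvals.min()), float(allvals.max())
        if hi == lo:
            log.warning(
                "sub-criterion %s has zero spread in the %s pool; normalizing to 1",
                sub.id, pool,
            )
            out.loc[sub.id] = 1.0
        elif sub.direction == BENEFIT:
            out.loc[sub.id] = (row - lo) / (hi - lo)
        else:
            out.loc[sub.id] = (hi - row) / (hi - lo)
    return NormalizedMatrix(matrix.assessment_id, out, group_of)


def wam(norm: NormalizedMatrix, ws: WeightSet) -> AggregateScores:
    """Weighted-sum aggregation of a normalized matrix.

    Every row must carry a propagated sub-criterion weight.  Group means are
    unweighted arithmetic means of each criterion group's normalized rows.
    """
    missing = [sid for sid in norm.data.index if sid not in ws.sub_weights]
    if missing:
        raise ScoreError(f"no sub-criterion weight for rows: {missing}")
    weights = pd.Series({sid: ws.sub_weights[sid] for sid in norm.data.index})
    scores = norm.data.mul(weights, axis=0).sum(axis=0)
    rows = []
    groups = sorted(set(norm.group_of.values()))
    for alt in norm.data.columns:
        rec = {"alternative": alt, "assessment": norm.assessment_id,
               "wam_score": float(scores[alt])}
        gmeans = {}
        for g in groups:
            gsubs = [sid for sid in norm.data.index if norm.group_of[sid] == g]
            gmeans[g] = float(norm.data.loc[gsubs, alt].mean()) if gsubs else np.nan
            rec[f"group_mean_{g}"] = gmeans[g]
        rec["table7_view"] = float(np.nanmean(list(gmeans.values())))
        rows.append(rec)
    return AggregateScores(pd.DataFrame(rows))


def score_pipeline(
    scores_I: ScoreMatrix,
    scores_II: ScoreMatrix,
    panel,
    hierarchy: CriteriaHierarchy,
    pool: str = THEORETICAL,
) -> tuple[AggregateScores, WeightSet]:
    """End-to-end scoring: SWARA weights -> normalize -> aggregate.

    Returns one aggregate score per alternative per assessment (including
    the healthy reference if present) together with the weight set used.
    """
    from .swara import compute_weights

    if set(scores_I.alternatives) != set(scores_II.alternatives):
        raise ScoreError(
            "assessments I and II must share the same alternative set; "
            f"difference: {set(scores_I.alternatives) ^ set(scores_II.alternatives)}"
        )
    ws = compute_weights(hierarchy, panel)
    both = [scores_I, scores_II]
    frames = []
    for m in both:
        others = [o for o in both if o is not m]
        norm = normalize(m, hierarchy, pool=pool, pool_matrices=others)
        frames.append(wam(norm, ws).frame)
    return AggregateScores(pd.concat(frames, ignore_index=True)), ws
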