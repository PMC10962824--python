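"""File formats and the end-to-end pipeline runner.

All tabular inputs and outputs are UTF-8 comma-separated files with a
mandatory header row and point decimals; the class models serialize to
JSON.  Readers return validated typed objects and preserve row/column
order; writers and readers round-trip to equal objects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (ClassModel, ExpertVotes, assign_class, class_distribution,
                       compare_models, corrected_value_set, expert_class_model,
                       kmeans_class_model, to_roman, from_roman)
from .hierarchy import CriteriaHierarchy, load_hierarchy
from .scoring import HEALTHY, THEORETICAL, AggregateScores, ScoreMatrix, score_pipeline
from .swara import ExpertPanel, WeightSet, compute_weights

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: empty input file")
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


# ---------------------------------------------------------------------------
# expert panel


def read_panel_csv(path: str | Path) -> ExpertPanel:
    """One row per expert, columns ``expert`` (optional) and ``pair_1..n``."""
    df = _read_csv(path)
    pair_cols = [c for c in df.columns if c.startswith("pair_")]
    if not pair_cols:
        raise SchemaError(f"{path}: expected pair_1..pair_n columns, got {list(df.columns)}")
    ids = tuple(df["expert"].astype(str)) if "expert" in df.columns else ()
    return ExpertPanel(df[pair_cols].to_numpy(float), expert_ids=ids)


def write_panel_csv(panel: ExpertPanel, path: str | Path) -> None:
    df = pd.DataFrame(
        panel.values, columns=[f"pair_{i+1}" for i in range(panel.n_pairs)]
    )
    df.insert(0, "expert", panel.expert_ids)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# raw score matrices (rows sub-criteria, columns alternatives)


def read_score_matrix_csv(
    path: str | Path, assessment_id: str, hierarchy: CriteriaHierarchy | None = None
) -> ScoreMatrix:
    df = _read_csv(path)
    if "sub_criterion" not in df.columns:
        raise SchemaError(f"{path}: first column must be 'sub_criterion'")
    df = df.set_index("sub_criterion")
    m = ScoreMatrix(assessment_id, df)
    if hierarchy is not None:
        m.validate(hierarchy)
    return m


def write_score_matrix_csv(matrix: ScoreMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = "sub_criterion"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# aggregate scores (one row per alternative, one column per assessment)


def read_aggregate_scores_csv(path: str | Path) -> pd.DataFrame:
    """Aggregate-score table to tidy form (patient, assessment, score)."""
    df = _read_csv(path)
    if "alternative" not in df.columns:
        raise SchemaError(f"{path}: missing 'alternative' column")
    acols = [c for c in df.columns if c.startswith("assessment_")]
    if not acols:
        raise SchemaError(f"{path}: no assessment_<id> columns found")
    df["alternative"] = df["alternative"].astype(str)
    out = df.melt(id_vars="alternative", value_vars=acols,
                  var_name="assessment", value_name="score")
    out["assessment"] = out["assessment"].str.replace("assessment_", "", regex=False)
    return out.rename(columns={"alternative": "patient"})


# ---------------------------------------------------------------------------
# expert votes


def read_votes_csv(path: str | Path) -> ExpertVotes:
    df = _read_csv(path)
    need = {"patient", "assessment", "reference"}
    if not need <= set(df.columns):
        raise SchemaError(f"{path}: votes table needs columns {sorted(need)}")
    df["patient"] = df["patient"].astype(str)
    for col in ["reference"] + [c for c in df.columns if c.startswith("expert_")]:
        if df[col].dtype == object:
            df[col] = df[col].map(from_roman)
        df[col] = df[col].astype(int)
    return ExpertVotes(df)


def write_votes_csv(votes: ExpertVotes, path: str | Path) -> None:
    out = votes.frame.copy()
    for col in ["reference"] + votes.vote_columns():
        out[col] = out[col].map(to_roman)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reports


def write_weight_table(ws: WeightSet, hierarchy: CriteriaHierarchy, path: str | Path) -> None:
    """Weight report: per criterion s, k, q, w and per sub-criterion weight."""
    rows = []
    for pos, cid in enumerate(ws.ranking):
        crit = hierarchy.criterion(cid)
        for sub in crit.effective_subs():
            rows.append({
                "criterion": cid,
                "direct_importance": crit.direct_importance,
                "s": ws.s[pos], "k": ws.k[pos], "q": ws.q[pos], "w": ws.w[pos],
                "sub_criterion": sub.id,
                "sub_weight": ws.sub_weights.get(sub.id, np.nan),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_class_model(model: ClassModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def read_class_model(path: str | Path) -> ClassModel:
    return ClassModel.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run.

    Either raw per-sub-criterion matrices (``scores_I``/``scores_II``) or an
    already aggregated score table (``aggregate_scores``) must be supplied;
    with raw matrices the aggregate scores are computed by the scoring
    stage.
    """

    out_dir: str | Path
    hierarchy_path: str | Path | None = None
    panel_path: str | Path | None = None
    scores_I_path: str | Path | None = None
    scores_II_path: str | Path | None = None
    aggregate_scores_path: str | Path | None = None
    votes_path: str | Path | None = None
    pool: str = THEORETICAL
    k: int = 5
    n_restarts: int = 50
    seed: int = 0
    rounding: int = 3

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("K must be >= 2")
        if self.rounding not in (3, 4):
            raise ValueError("rounding must be 3 or 4 decimals")


def run_pipeline(config: RunConfig) -> dict:
    """Weights -> scoring -> classification -> comparison, with a report bundle.

    Writes the weight table, score table, per-patient class report, boundary
    table and both class models into ``config.out_dir`` and returns the
    in-memory results.  All randomness is controlled by ``config.seed``.
    """
    from . import datasets

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("rehabmcdm")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results: dict = {}
    try:
        hierarchy = (load_hierarchy(config.hierarchy_path)
                     if config.hierarchy_path else datasets.default_hierarchy())
        panel = (read_panel_csv(config.panel_path)
                 if config.panel_path else datasets.default_expert_panel())
        log.info("stage weights: panel %d experts x %d pairs, %d criteria",
                 panel.n_experts, panel.n_pairs, len(hierarchy.criteria))
        ws = compute_weights(hierarchy, panel)
        write_weight_table(ws, hierarchy, out / "weights.csv")
        results["weights"] = ws
        log.info("stage weights: top weight %s=%.4f", ws.ranking[0], ws.w[0])

        if config.scores_I_path and config.scores_II_path:
            m1 = read_score_matrix_csv(config.scores_I_path, "I", hierarchy)
            m2 = read_score_matrix_csv(config.scores_II_path, "II", hierarchy)
            log.info("stage scoring: %d alternatives, pool=%s",
                     len(m1.alternatives), config.pool)
            agg, _ = score_pipeline(m1, m2, panel, hierarchy, pool=config.pool)
            agg.frame.to_csv(out / "scores.csv", index=False)
            scores = agg.frame.rename(
                columns={"alternative": "patient", "wam_score": "score"}
            )[["patient", "assessment", "score"]]
            results["aggregate_scores"] = agg
        elif config.aggregate_scores_path:
            scores = read_aggregate_scores_csv(config.aggregate_scores_path)
            scores.to_csv(out / "scores.csv", index=False)
        else:
            scores = datasets.cohort_scores()
            scores.to_csv(out / "scores.csv", index=False)
        results["scores"] = scores

        votes = (read_votes_csv(config.votes_path)
                 if config.votes_path else datasets.cohort_expert_votes())
        patient_scores = scores[scores["patient"] != HEALTHY]
        healthy_scores = scores[scores["patient"] == HEALTHY]["score"]
        if len(healthy_scores) == 0:
            healthy_scores = pd.Series([1.0])
        values = corrected_value_set(
            scores[scores["assessment"] == "I"]["score"],
            scores[scores["assessment"] == "II"]["score"],
        )
        log.info("stage classification: %d corrected values, K=%d, restarts=%d, seed=%d",
                 len(values), config.k, config.n_restarts, config.seed)
        km_model = kmeans_class_model(values, k=config.k,
                                      n_restarts=config.n_restarts,
                                      seed=config.seed, rounding=config.rounding)
        ex_model = expert_class_model(votes, patient_scores,
                                      healthy_scores=tuple(healthy_scores),
                                      k=config.k, rounding=config.rounding)
        write_class_model(km_model, out / "class_model_kmeans.json")
        write_class_model(ex_model, out / "class_model_expert.json")
        results["kmeans_model"], results["expert_model"] = km_model, ex_model

        report = patient_scores.copy()
        report["expert_class"] = report["score"].map(lambda s: assign_class(s, ex_model))
        report["kmeans_class"] = report["score"].map(lambda s: assign_class(s, km_model))
        report["agree"] = report["expert_class"] == report["kmeans_class"]
        report.to_csv(out / "class_report.csv", index=False)
        results["class_report"] = report

        comparison = compare_models(ex_model, km_model, patient_scores["score"])
        results["comparison"] = comparison
        pd.DataFrame({
            "class": [to_roman(i + 1) for i in range(config.k)],
            "expert_lo": [iv[0] for iv in ex_model.intervals],
            "expert_hi": [iv[1] for iv in ex_model.intervals],
            "kmeans_lo": [iv[0] for iv in km_model.intervals],
            "kmeans_hi": [iv[1] for iv in km_model.intervals],
        }).to_csv(out / "boundaries.csv", index=False)
        for aid in dict.fromkeys(patient_scores["assessment"]):
            counts = class_distribution(
                patient_scores[patient_scores["assessment"] == aid]["score"], ex_model
            )
            log.info("stage comparison: assessment %s expert-class counts %s",
                     aid, counts.tolist())
        log.info("stage comparison: agreement %.4f", comparison.agreement)
        return results
    finally:
        root.removeHandler(handler)
        handler.close()
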