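"""Packaged reference inputs: the default criteria system, the 12-expert
pairwise panel, the cohort's printed aggregate scores and expert class
labels, and the published class-boundary models."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classify import ClassModel, ExpertVotes, from_roman
from .hierarchy import CriteriaHierarchy, load_hierarchy
from .swara import ExpertPanel


def _data_path(name: str):
    return resources.files("rehabmcdm.data").joinpath(name)


def default_hierarchy() -> CriteriaHierarchy:
    """The packaged criteria system: 3 groups, 10 criteria, ordinal scales."""
    with resources.as_file(_data_path("default_hierarchy.json")) as p:
        return load_hierarchy(p)


def default_expert_panel() -> ExpertPanel:
    """Adjacent-pair comparative importances of the 12-expert panel."""
    df = pd.read_csv(_data_path("expert_panel.csv"))
    pair_cols = [c for c in df.columns if c.startswith("pair_")]
    return ExpertPanel(df[pair_cols].to_numpy(float),
                       expert_ids=tuple(df["expert"].astype(str)))


def cohort_scores(long: bool = True) -> pd.DataFrame:
    """Aggregate recovery scores of the 20-patient cohort plus the healthy
    reference, at assessments I and II.

    Long format has columns ``patient``, ``assessment`` ('I'/'II') and
    ``score``; wide format one row per alternative.
    """
    df = pd.read_csv(_data_path("cohort_scores.csv"), dtype={"alternative": str})
    if not long:
        return df
    out = df.melt(id_vars="alternative", var_name="assessment", value_name="score")
    out["assessment"] = out["assessment"].str.replace("assessment_", "", regex=False)
    return out.rename(columns={"alternative": "patient"})


def cohort_expert_votes() -> ExpertVotes:
    """Recorded class labels and the three individual expert votes per
    patient and assessment."""
    df = pd.read_csv(_data_path("expert_votes.csv"), dtype={"patient": str})
    for col in ("reference", "expert_1", "expert_2", "expert_3"):
        df[col] = df[col].map(from_roman)
    return ExpertVotes(df)


def expert_boundaries() -> ClassModel:
    """Published five-class boundaries from the expert calibration."""
    return ClassModel(
        intervals=((0.0100, 0.3168), (0.3169, 0.491), (0.492, 0.668),
                   (0.6692, 0.8179), (0.818, 1.0)),
        provenance="expert",
    )


def kmeans_boundaries() -> ClassModel:
    """Published five-class boundaries from the K-Means calibration of the
    corrected value set."""
    return ClassModel(
        intervals=((0.0100, 0.2934), (0.2935, 0.491), (0.492, 0.668),
                   (0.669, 0.8179), (0.818, 1.0)),
        provenance="kmeans",
    )
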