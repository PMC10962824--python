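"""Synthetic expert panels and two-assessment patient cohorts.

The clinical dataset behind the packaged aggregate scores is not public, so
this module generates cohorts with the statistical structure the pipeline
assumes: each patient carries a latent recovery state in [0, 1] (1 =
healthy) drawn around the centre of their true impairment class, ordinal
sub-criterion scores are a deterministic monotone quantization of that
latent state (equal-width thresholds per scale, respecting each
sub-criterion's benefit/cost direction), the second assessment shifts the
latent state by an improvement term, and expert class votes are the true
class with optional +/-1 confusion noise.

Defaults emulate the study cohort: 20 patients, intake classes II/III in
65/35 proportion, an improvement of one class width (0.2) between the two
assessments, and a 12-expert panel whose pair values scatter around the
packaged panel's averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import ClassModelError, ExpertVotes, compare_models, expert_class_model, \
    kmeans_class_model, assign_class, corrected_value_set
from .hierarchy import BENEFIT, CriteriaHierarchy
from .scoring import HEALTHY, ScoreMatrix, healthy_reference_column, normalize, wam
from .swara import ExpertPanel, average_pair_values, propagate_sub_weights, \
    rank_by_direct_importance, swara_weights


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for a two-assessment synthetic cohort."""

    n_patients: int = 20
    true_class_proportions: tuple[float, ...] = (0.0, 0.65, 0.35, 0.0, 0.0)
    improvement_shift: float = 0.2
    noise_sd: float = 0.05
    vote_noise: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        p = np.asarray(self.true_class_proportions, float)
        if len(p) != 5 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("true_class_proportions must be 5 non-negative values summing to 1")


@dataclass(frozen=True)
class PanelSpec:
    """Generative settings for a synthetic expert panel."""

    n_experts: int = 12
    true_s: tuple[float, ...] = (0.5417, 0.5058, 0.2417, 0.6975, 0.2333,
                                 0.7592, 0.4442, 0.2683, 0.6892)
    expert_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        s = np.asarray(self.true_s, float)
        if ((s < 0) | (s > 1)).any():
            raise ValueError("true_s values must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticCohort:
    scores_I: ScoreMatrix
    scores_II: ScoreMatrix
    votes: ExpertVotes
    truth: pd.DataFrame  # patient, assessment, latent, true_class


@dataclass(frozen=True)
class RecoveryReport:
    """Per-replicate outcomes of a full-pipeline recovery experiment."""

    weight_error: np.ndarray  # max |w_hat - w_true| per replicate
    class_accuracy: np.ndarray  # fraction of patient-assessments classified to true class
    boundary_agreement: np.ndarray  # expert vs kmeans identical-classification fraction
    n_reps: int

    def summary(self) -> dict[str, float]:
        def ci(x):
            return 1.96 * float(np.std(x, ddof=1)) / np.sqrt(len(x)) if len(x) > 1 else 0.0

        return {
            "mean_weight_error": float(np.mean(self.weight_error)),
            "mean_class_accuracy": float(np.mean(self.class_accuracy)),
            "class_accuracy_ci95": ci(self.class_accuracy),
            "mean_boundary_agreement": float(np.nanmean(self.boundary_agreement)),
            "n_reps": self.n_reps,
        }


CLASS_CENTERS = np.array([0.1, 0.3, 0.5, 0.7, 0.9])  # equal fifths of [0, 1]


def latent_to_level(latent: float, n_levels: int, direction: str) -> int:
    """Deterministic equal-width quantization of a latent state to a scale.

    Monotone by construction: a healthier latent never maps to a worse
    ordinal level, on benefit scales (higher points better) or cost scales
    (lower points better).
    """
    step = min(n_levels - 1, int(np.floor(np.clip(latent, 0.0, 1.0) * n_levels)))
    return 1 + step if direction == BENEFIT else n_levels - step


def class_of_latent(latent: float) -> int:
    """True impairment class = the fifth of [0, 1] holding the latent."""
    return int(min(5, np.floor(np.clip(latent, 0.0, 1.0) * 5) + 1))


def gen_expert_panel(spec: PanelSpec) -> ExpertPanel:
    """Pair values = clip(true_s + noise, 0, 1) rounded to 2 decimals."""
    rng = np.random.default_rng(spec.seed)
    true_s = np.asarray(spec.true_s, float)
    vals = true_s + rng.normal(0.0, spec.expert_noise_sd, size=(spec.n_experts, len(true_s)))
    return ExpertPanel(np.round(np.clip(vals, 0.0, 1.0), 2))


def gen_cohort(spec: CohortSpec, hierarchy: CriteriaHierarchy) -> SyntheticCohort:
    """Draw a two-assessment cohort plus synthetic expert votes."""
    rng = np.random.default_rng(spec.seed)
    classes_I = rng.choice(5, size=spec.n_patients, p=spec.true_class_proportions) + 1
    latent_I = np.clip(
        CLASS_CENTERS[classes_I - 1] + rng.normal(0.0, spec.noise_sd, spec.n_patients),
        0.0, 1.0,
    )
    latent_II = np.clip(
        latent_I + spec.improvement_shift + rng.normal(0.0, spec.noise_sd, spec.n_patients),
        0.0, 1.0,
    )
    patients = [f"p{i+1}" for i in range(spec.n_patients)]
    subs = list(hierarchy.iter_subs())

    def matrix(latents, assessment_id):
        cols = {
            pid: {
                s.id: latent_to_level(lat, s.n_levels(), s.direction)
                for _, s in subs
            }
            for pid, lat in zip(patients, latents)
        }
        df = pd.DataFrame(cols)
        df[HEALTHY] = healthy_reference_column(hierarchy)
        return ScoreMatrix(assessment_id, df.loc[[s.id for _, s in subs]])

    truth_rows, vote_rows = [], []
    for aid, latents in (("I", latent_I), ("II", latent_II)):
        for pid, lat in zip(patients, latents):
            # truth is the impairment band actually occupied by the latent
            # state (identical to the drawn class in the noiseless limit)
            cls = class_of_latent(lat)
            truth_rows.append(
                {"patient": pid, "assessment": aid, "latent": float(lat), "true_class": cls}
            )
            votes = []
            for _ in range(3):
                v = cls
                if spec.vote_noise > 0 and rng.random() < spec.vote_noise:
                    v = int(np.clip(cls + rng.choice([-1, 1]), 1, 5))
                votes.append(v)
            counts = pd.Series(votes).value_counts()
            ref = int(min(counts[counts == counts.max()].index))
            vote_rows.append(
                {"patient": pid, "assessment": aid, "reference": ref,
                 "expert_1": votes[0], "expert_2": votes[1], "expert_3": votes[2]}
            )
    return SyntheticCohort(
        scores_I=matrix(latent_I, "I"),
        scores_II=matrix(latent_II, "II"),
        votes=ExpertVotes(pd.DataFrame(vote_rows)),
        truth=pd.DataFrame(truth_rows),
    )


def recovery_experiment(
    cohort_spec: CohortSpec,
    panel_spec: PanelSpec,
    hierarchy: CriteriaHierarchy,
    n_reps: int = 50,
    seed: int = 0,
) -> RecoveryReport:
    """Run the full pipeline repeatedly on generated data.

    Per replicate: generate a panel and cohort, compute SWARA weights and
    aggregate scores (theoretical pooling), calibrate a five-class K-Means
    model on the corrected value set and an expert model from the synthetic
    votes, then record (a) the weight-recovery error max|w_hat - w_true|
    against the weights implied by the panel's true s-vector, (b) the
    fraction of patient-assessments whose calibrated class equals the true
    class, and (c) the expert-vs-K-Means classification agreement.
    """
    ranking = rank_by_direct_importance(hierarchy)
    w_true = swara_weights(np.asarray(panel_spec.true_s), ranking).w
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_reps) % (2**31)
    weight_err, accuracy, agreement = [], [], []
    for rep in range(n_reps):
        panel = gen_expert_panel(replace(panel_spec, seed=int(child_seeds[2 * rep])))
        cohort = gen_cohort(replace(cohort_spec, seed=int(child_seeds[2 * rep + 1])), hierarchy)
        ws = propagate_sub_weights(
            swara_weights(average_pair_values(panel), ranking), hierarchy
        )
        weight_err.append(float(np.max(np.abs(ws.w - w_true))))
        frames = [
            wam(normalize(m, hierarchy), ws).frame
            for m in (cohort.scores_I, cohort.scores_II)
        ]
        agg = pd.concat(frames, ignore_index=True)
        patient_rows = agg[agg["alternative"] != HEALTHY]
        healthy_rows = agg[agg["alternative"] == HEALTHY]
        values = corrected_value_set(
            agg[agg["assessment"] == "I"]["wam_score"],
            agg[agg["assessment"] == "II"]["wam_score"],
        )
        # one interval per class actually represented in the corrected set:
        # the anchors stand in for class 1 (added 0.01) and class 5 (healthy)
        present = sorted(set(cohort.truth["true_class"]) | {1, 5})
        km_model = kmeans_class_model(values, k=len(present),
                                      seed=int(child_seeds[2 * rep + 1]))
        merged = patient_rows.rename(columns={"alternative": "patient"}).merge(
            cohort.truth, on=["patient", "assessment"]
        )
        assigned = merged["wam_score"].map(
            lambda s: present[assign_class(s, km_model) - 1]
        )
        accuracy.append(float((assigned == merged["true_class"]).mean()))
        scores_tidy = patient_rows.rename(
            columns={"alternative": "patient", "wam_score": "score"}
        )[["patient", "assessment", "score"]]
        try:
            ex_model = expert_class_model(
                cohort.votes, scores_tidy,
                healthy_scores=tuple(healthy_rows["wam_score"]),
                classes=present,
            )
        except ClassModelError:
            # with small cohorts and vote noise a present class may receive
            # no expert label at all; no expert boundary exists that replicate
            agreement.append(np.nan)
        else:
            agreement.append(
                compare_models(ex_model, km_model, patient_rows["wam_score"]).agreement
            )
    return RecoveryReport(
        weight_error=np.array(weight_err),
        class_accuracy=np.array(accuracy),
        boundary_agreement=np.array(agreement),
        n_reps=n_reps,
    )
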