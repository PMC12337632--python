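"""Five-group patient stratification and k-NN outcome prediction.

Patients are partitioned on (AF type, complexity score): paroxysmal
patients split at score 0.4 and 0.6 into low / intermediate / high
complexity, persistent patients split at 0.5 into low / high — five groups
in total. Outcome prediction uses a k-nearest-neighbour vote (k = 5) in an
encoded feature space of AF type (one-hot), standardized score and
treatment class (rhythm vs rate control, one-hot); the comparator is the
conventional temporal ("3-P") classification that predicts each AF-type
stratum's majority outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "GROUP_LABELS",
    "PatientRecord",
    "ClusterModel",
    "treatment_class",
    "assign_group",
    "assign_groups",
    "fit_knn",
    "predict_outcome",
    "baseline_3p_predict",
]

AF_TYPES = ("paroxysmal", "persistent")
TREATMENTS = ("ablation_pvi", "ablation_pvi_drivers", "pharma_rhythm", "rate_control")
# group id -> label: paroxysmal low/intermediate/high, persistent low/high
GROUP_LABELS = {1: "P-low", 2: "P-mid", 3: "P-high", 4: "S-low", 5: "S-high"}


def treatment_class(treatment: str) -> str:
    """Rhythm- vs rate-control class of a treatment category."""
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    return "rate" if treatment == "rate_control" else "rhythm"


@dataclass
class PatientRecord:
    """One patient: AF type, treatment, biomarkers, score and outcome."""

    af_type: str
    treatment: str
    score: float | None = None
    hdf: float | None = None
    median_df: float | None = None
    mean_rotor_time: float | None = None
    outcome_1y: int | None = None  # 1 = freedom from AF at 1 year
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.af_type not in AF_TYPES:
            raise ValueError(f"unknown AF type {self.af_type!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")

    @property
    def treatment_class(self) -> str:
        return treatment_class(self.treatment)


def assign_group(
    af_type: str,
    score: float,
    parox_cuts: tuple[float, float] = (0.4, 0.6),
    persist_cut: float = 0.5,
) -> int:
    """Stratification group (1-5) of one patient.

    Paroxysmal: score < 0.4 -> group 1 (P-low); 0.4 <= score <= 0.6 ->
    group 2 (P-mid); score > 0.6 -> group 3 (P-high). Persistent:
    score < 0.5 -> group 4 (S-low); score >= 0.5 -> group 5 (S-high).
    Every (AF type, score) pair receives exactly one label.
    """
    if af_type not in AF_TYPES:
        raise ValueError(f"missing or unknown AF type {af_type!r}")
    lo, hi = parox_cuts
    if af_type == "paroxysmal":
        if score < lo:
            return 1
        if score <= hi:
            return 2
        return 3
    return 4 if score < persist_cut else 5


def assign_groups(cohort: pd.DataFrame, score_col: str = "score", **kw) -> pd.Series:
    """Vectorised :func:`assign_group` over a cohort DataFrame."""
    return pd.Series(
        [assign_group(a, s, **kw) for a, s in zip(cohort["af_type"], cohort[score_col])],
        index=cohort.index,
        name="group",
    )


@dataclass
class ClusterModel:
    """Fitted k-NN outcome predictor over encoded patient features."""

    k: int
    nn: NearestNeighbors
    train_outcomes: np.ndarray
    score_mean: float
    score_std: float
    feature_names: list[str] = field(default_factory=list)

    def encode(self, af_type, score, treat_class) -> np.ndarray:
        af_type = np.atleast_1d(np.asarray(af_type))
        score = np.atleast_1d(np.asarray(score, dtype=float))
        treat_class = np.atleast_1d(np.asarray(treat_class))
        for a in af_type:
            if a not in AF_TYPES:
                raise ValueError(f"unknown AF type {a!r}")
        for t in treat_class:
            if t not in ("rhythm", "rate"):
                raise ValueError(f"unknown treatment class {t!r}")
        z = (score - self.score_mean) / self.score_std
        return np.column_stack(
            [
                (af_type == "paroxysmal").astype(float),
                (af_type == "persistent").astype(float),
                z,
                (np.asarray(treat_class) == "rhythm").astype(float),
                (np.asarray(treat_class) == "rate").astype(float),
            ]
        )


def fit_knn(train: pd.DataFrame, k: int = 5, score_col: str = "score") -> ClusterModel:
    """Fit the k-NN predictor on a labelled training cohort.

    Features: AF type one-hot, score z-standardized on the training set,
    treatment class one-hot; Euclidean metric. With odd ``k`` on a binary
    outcome the neighbour vote cannot tie; if it could (even ``k``), ties
    break pessimistically toward AF recurrence (outcome 0).
    """
    if k > len(train):
        raise ValueError("k exceeds training-set size")
    y = train["outcome_1y"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training outcomes must include both classes")
    scores = train[score_col].to_numpy(dtype=float)
    mu, sd = float(scores.mean()), float(scores.std())
    sd = sd if sd > 0 else 1.0
    model = ClusterModel(
        k=k,
        nn=NearestNeighbors(n_neighbors=k),
        train_outcomes=y,
        score_mean=mu,
        score_std=sd,
        feature_names=["parox", "persist", "score_z", "rhythm", "rate"],
    )
    tclass = train["treatment"].map(treatment_class).to_numpy()
    X = model.encode(train["af_type"].to_numpy(), scores, tclass)
    model.nn.fit(X)
    return model


def predict_outcome(model: ClusterModel, patients: pd.DataFrame, score_col: str = "score"
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote of the k nearest training neighbours.

    Returns ``(predicted_outcome, vote_fraction)`` where the fraction is
    the share of neighbours voting for freedom from AF (multiples of 1/k).
    """
    tclass = patients["treatment"].map(treatment_class).to_numpy()
    X = model.encode(patients["af_type"].to_numpy(), patients[score_col].to_numpy(), tclass)
    _, idx = model.nn.kneighbors(X)
    votes = model.train_outcomes[idx]
    frac = votes.mean(axis=1)
    # strict majority predicts freedom; exact ties (even k) fall to AF
    pred = (frac > 0.5).astype(int)
    return pred, frac


def baseline_3p_predict(train: pd.DataFrame, patients: pd.DataFrame) -> np.ndarray:
    """Conventional paroxysmal/persistent comparator.

    Predicts, for each patient, the majority outcome of their AF-type
    stratum in the training cohort; an exact 50/50 stratum predicts AF
    recurrence (the declared pessimistic tie rule).
    """
    majority = {}
    for af, grp in train.groupby("af_type"):
        rate = grp["outcome_1y"].mean()
        majority[af] = int(rate > 0.5)
    preds = []
    for af in patients["af_type"]:
        if af not in majority:
            raise ValueError(f"AF type {af!r} unseen in training data")
        preds.append(majority[af])
    return np.asarray(preds, dtype=int)
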