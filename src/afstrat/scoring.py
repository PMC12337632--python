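"""The ECGI complexity score and its logistic calibration.

The score is a logistic model of the 1-year rhythm outcome on three ECGI
biomarkers — highest dominant frequency (HDF, Hz), median dominant
frequency (Median DF, Hz) and mean rotor time (s):

    P = 1 / (1 + exp(-(b0 + b1*HDF + b2*MedianDF + b3*MeanRotorTime)))

with published coefficients b0 = -0.11, b1 = +0.40, b2 = -0.39,
b3 = -0.04: higher HDF raises the score (more complex fibrillation), while
higher Median DF and longer mean rotor time lower it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "BiomarkerVector",
    "ScoreCoefficients",
    "complexity_score",
    "calibrate_coefficients",
    "select_features",
    "PerfectSeparationError",
]

BIOMARKER_COLUMNS = ["hdf", "median_df", "mean_rotor_time"]


class PerfectSeparationError(RuntimeError):
    """Raised when the outcome is perfectly separated in biomarker space."""


@dataclass
class BiomarkerVector:
    """ECGI biomarkers for one patient (one averaged recording)."""

    hdf_hz: float
    median_df_hz: float
    mean_rotor_time_s: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hdf_hz < self.median_df_hz - 1e-9:
            raise ValueError("HDF must be >= Median DF")
        if min(self.hdf_hz, self.median_df_hz, self.mean_rotor_time_s) < 0:
            raise ValueError("biomarkers must be nonnegative")


@dataclass
class ScoreCoefficients:
    """Per-unit log-odds coefficients of the complexity score."""

    intercept: float = -0.11
    beta_hdf: float = 0.40
    beta_median_df: float = -0.39
    beta_mean_rotor_time: float = -0.04
    standard_errors: dict | None = None

    def __post_init__(self) -> None:
        vals = [self.intercept, self.beta_hdf, self.beta_median_df, self.beta_mean_rotor_time]
        if not np.all(np.isfinite(vals)):
            raise ValueError("coefficients must be finite")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreCoefficients":
        with open(path) as fh:
            return cls(**json.load(fh))


def _extract(b) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(b, BiomarkerVector):
        return (np.asarray(b.hdf_hz), np.asarray(b.median_df_hz),
                np.asarray(b.mean_rotor_time_s))
    if isinstance(b, pd.DataFrame):
        return (b["hdf"].to_numpy(), b["median_df"].to_numpy(),
                b["mean_rotor_time"].to_numpy())
    if isinstance(b, dict):
        return (np.asarray(b["hdf_hz"]), np.asarray(b["median_df_hz"]),
                np.asarray(b["mean_rotor_time_s"]))
    raise TypeError("expected BiomarkerVector, DataFrame or dict")


def complexity_score(biomarkers, coefficients: ScoreCoefficients | None = None):
    """Evaluate the logistic complexity score; vectorised over patients.

    Accepts a :class:`BiomarkerVector`, a cohort DataFrame (columns ``hdf``,
    ``median_df``, ``mean_rotor_time``) or a dict of arrays. Returns P in
    (0, 1) with the same shape as the inputs.
    """
    c = coefficients if coefficients is not None else ScoreCoefficients()
    hdf, mdf, mrt = _extract(biomarkers)
    z = (c.intercept + c.beta_hdf * hdf + c.beta_median_df * mdf
         + c.beta_mean_rotor_time * mrt)
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if np.ndim(out) == 0 else out


def calibrate_coefficients(cohort: pd.DataFrame, outcome_col: str = "outcome_1y"
                           ) -> ScoreCoefficients:
    """Maximum-likelihood logistic refit of the score on a labelled cohort.

    Fits outcome ~ HDF + MedianDF + MeanRotorTime and returns the estimated
    coefficients with their standard errors attached. Raises
    :class:`PerfectSeparationError` (naming the separating direction) when
    the classes are linearly separable in biomarker space.
    """
    y = cohort[outcome_col].to_numpy(dtype=float)
    if len(y) < 20:
        raise ValueError("need n >= 20 for calibration")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(cohort[BIOMARKER_COLUMNS].to_numpy(dtype=float))
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = model.fit(disp=False, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError, RuntimeWarning,
            np.linalg.LinAlgError) as exc:
        direction = _separating_direction(X[:, 1:], y)
        raise PerfectSeparationError(
            "perfect separation of outcomes along direction "
            f"(hdf, median_df, mean_rotor_time) ~ {np.round(direction, 3).tolist()}"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic calibration did not converge")
    b = res.params
    se = res.bse
    names = ["intercept", "beta_hdf", "beta_median_df", "beta_mean_rotor_time"]
    return ScoreCoefficients(
        intercept=float(b[0]), beta_hdf=float(b[1]), beta_median_df=float(b[2]),
        beta_mean_rotor_time=float(b[3]),
        standard_errors=dict(zip(names, (float(v) for v in se))),
    )


def _separating_direction(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    # difference of class means, normalised: the direction along which a
    # separated outcome splits
    d = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
    n = np.linalg.norm(d)
    return d / n if n > 0 else d


def select_features(cohort: pd.DataFrame, candidates: list[str], k: int = 3,
                    outcome_col: str = "outcome_1y") -> list[str]:
    """Rank candidate biomarkers by univariate discrimination of the outcome.

    Each candidate column is scored by its univariate AUC against the
    outcome, folded about 0.5 (direction-free); the top ``k`` names are
    returned in decreasing order. Constant columns carry no information and
    are excluded with a warning.
    """
    from sklearn.metrics import roc_auc_score

    if len(candidates) < k:
        raise ValueError("fewer candidates than k")
    y = cohort[outcome_col].to_numpy()
    scores = {}
    for name in candidates:
        x = cohort[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"feature {name!r} is constant; excluded", stacklevel=2)
            continue
        auc = roc_auc_score(y, x)
        scores[name] = abs(auc - 0.5)
    ranked = sorted(scores, key=lambda n: (-scores[n], n))
    return ranked[:k]
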