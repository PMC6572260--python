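"""Affine autocalibration of predicted retention times.

Small errors in the instrument parameters (dead time t0, dwell time tD,
steepness b via the ramp duration) propagate, to first order, into a
*global affine* transformation of every predicted retention time:

    tR_pred = alpha * tR_obs + beta

with alpha and beta shared by all compounds.  (The derivation keeps the
first-order terms in delta-t0/t0, delta-tD and delta-b/b and discards a
1/k0 term, negligible because the initial retention k0 in gradient RPLC is
of order 10^3.)  Fitting (alpha, beta) on a handful of compounds of known
identity — calibrants — therefore corrects the whole library at once:

    tR_calibrated = (tR_pred - beta) / alpha

Calibrants should carry experimentally measured (ln kw, S); calibrating
with in-silico (QSRR) parameters propagates their prediction error into
every corrected time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationFit",
    "PerturbationSpec",
    "InsufficientCalibrantsError",
    "fit_affine",
    "apply_calibration",
]


class InsufficientCalibrantsError(ValueError):
    """Fewer than two calibrants, or degenerate observed times."""


@dataclass(frozen=True)
class CalibrationFit:
    """Result of the affine prediction-vs-observation regression.

    ``residuals[i] = pred_i - (alpha*obs_i + beta)`` in minutes.
    """

    alpha: float
    beta: float
    n_calibrants: int
    residuals: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_calibrants < 2:
            raise InsufficientCalibrantsError(
                f"calibration needs >= 2 calibrants, got {self.n_calibrants}"
            )
        if self.alpha <= 0.0:
            warnings.warn(
                f"calibration slope alpha={self.alpha:.4g} is not positive; "
                "the fit is not physically meaningful",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PerturbationSpec:
    """Relative perturbations of the instrument parameters (t0, tD, b).

    Used to emulate mis-specified instrument geometry; magnitudes are
    capped at 20% because the affine-covariance argument is first order.
    """

    rel_dt0: float = 0.0
    rel_dtD: float = 0.0
    rel_db: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rel_dt0", "rel_dtD", "rel_db"):
            v = getattr(self, name)
            if abs(v) > 0.2:
                raise ValueError(f"|{name}| must be <= 0.2 for linearisation, got {v}")


def fit_affine(pred, obs) -> CalibrationFit:
    """Least-squares fit of predictions on observations: pred = alpha*obs + beta.

    Parameters
    ----------
    pred, obs : array-like, same length >= 2
        Predicted and observed retention times (min) of the calibrants.

    Notes
    -----
    The regression direction (prediction on observation) follows the model
    statement that predictions made with slightly wrong instrument
    parameters are an affine image of the true times; at the near-perfect
    correlations where calibration is useful the direction is immaterial.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be equal-length 1-D sequences")
    n = pred.size
    if n < 2:
        raise InsufficientCalibrantsError(f"calibration needs >= 2 calibrants, got {n}")
    if np.ptp(obs) == 0.0:
        raise InsufficientCalibrantsError(
            "observed calibrant times are all identical; slope is undetermined"
        )
    design = np.column_stack([obs, np.ones(n)])
    (alpha, beta), *_ = np.linalg.lstsq(design, pred, rcond=None)
    residuals = pred - (alpha * obs + beta)
    return CalibrationFit(
        alpha=float(alpha), beta=float(beta), n_calibrants=n, residuals=residuals
    )


def apply_calibration(t_pred, fit: CalibrationFit):
    """Correct predicted time(s): tR_calibrated = (tR_pred - beta) / alpha.

    Accepts a scalar or array; returns the same shape.
    """
    if fit.alpha == 0.0:
        raise ZeroDivisionError("calibration slope alpha is zero")
    t_pred = np.asarray(t_pred, dtype=float)
    out = (t_pred - fit.beta) / fit.alpha
    return float(out) if out.ndim == 0 else out
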