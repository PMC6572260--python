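"""Simulation protocols for evaluating prediction and calibration accuracy.

The central protocol mirrors how retention prediction is validated in
practice: take a library of compounds with known LSS parameters, treat
the model's own predictions under the *true* instrument parameters as the
observed times, recompute predictions under slightly mis-specified
instrument parameters (a few percent on dead time, dwell time and ramp
duration), autocalibrate on a handful of calibrants spread across the
elution range, and measure the residual relative errors on the held-out
compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibration import apply_calibration, fit_affine
from .lss import retention_time
from .synthetic import SyntheticScenario, gen_library, true_retention_times

__all__ = ["CalibrationBenchmarkResult", "calibration_benchmark"]

#: elution-range quantiles at which the calibrants are taken
CALIBRANT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class CalibrationBenchmarkResult:
    """Held-out relative errors (fractions) before and after calibration."""

    rel_errors_calibrated: np.ndarray
    rel_errors_uncalibrated: np.ndarray
    alpha: float
    beta: float
    n_holdout: int

    @property
    def max_rel_error_pct(self) -> float:
        return float(self.rel_errors_calibrated.max() * 100.0)

    @property
    def pct_below(self) -> float:
        """Percentage of held-out compounds with relative error < 0.4%."""
        return float((self.rel_errors_calibrated < 0.004).mean() * 100.0)


def calibration_benchmark(
    seed: int,
    *,
    n_compounds: int = 70,
    instrument_scale: float = 1.03,
    quantiles: tuple[float, ...] = CALIBRANT_QUANTILES,
) -> CalibrationBenchmarkResult:
    """Perturb-then-calibrate benchmark on a synthetic library.

    Observed times come from the true gradient; predictions use a gradient
    whose dead time, dwell time and ramp duration are each scaled by
    ``instrument_scale``.  Five calibrants are taken at the 10/30/50/70/90th
    percentiles of the observed elution range, the affine fit is applied
    to the remaining compounds, and held-out relative errors are returned.
    """
    scenario = SyntheticScenario(seed=seed, n_compounds=n_compounds)
    library = gen_library(scenario)
    g = scenario.gradient
    observed = true_retention_times(library, g)
    g_wrong = replace(
        g,
        t_dead=g.t_dead * instrument_scale,
        t_dwell=g.t_dwell * instrument_scale,
        t_gradient=g.t_gradient * instrument_scale,
    )
    predicted = np.array([retention_time(c.lss, g_wrong) for c in library.compounds])

    order = np.argsort(observed)
    cal_idx = np.unique([order[int(round(q * (n_compounds - 1)))] for q in quantiles])
    holdout = np.setdiff1d(np.arange(n_compounds), cal_idx)

    fit = fit_affine(predicted[cal_idx], observed[cal_idx])
    calibrated = apply_calibration(predicted[holdout], fit)
    rel_cal = np.abs(calibrated - observed[holdout]) / observed[holdout]
    rel_raw = np.abs(predicted[holdout] - observed[holdout]) / observed[holdout]
    return CalibrationBenchmarkResult(
        rel_errors_calibrated=rel_cal,
        rel_errors_uncalibrated=rel_raw,
        alpha=fit.alpha,
        beta=fit.beta,
        n_holdout=holdout.size,
    )
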