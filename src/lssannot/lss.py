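"""Linear solvent strength (LSS) retention model for gradient reversed-phase LC.

The LSS model describes how an analyte's retention factor responds to the
volume fraction ``phi`` of strong (organic) solvent in a binary mobile phase:

    k(phi) = kw * exp(-S * phi)

where ``kw`` is the retention factor extrapolated to pure weak solvent
(water) and ``S`` is the solvent-strength slope.  Under a single linear
gradient ramp ``phi0 -> phi0 + delta_phi`` over ``t_gradient`` minutes, with
column dead time ``t_dead`` and system dwell time ``t_dwell``, the elution
time of an analyte has a closed form (see :func:`retention_time`).  A direct
numerical integration of the migration equation is provided as an
independent oracle (:func:`migrate_oracle`).

Units and conventions
---------------------
* all times in minutes, ``phi`` dimensionless in [0, 1];
* ``ln_kw`` and ``S`` are in *natural*-log units (the retention law uses a
  natural exponent).  Much of the chromatographic literature tabulates
  ``log10 kw`` and a base-10 slope; convert by multiplying both by ln(10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GradientProgram",
    "LSSParams",
    "RetentionDomainError",
    "OracleConvergenceError",
    "retention_factor",
    "gradient_steepness",
    "retention_time",
    "retention_times",
    "migrate_oracle",
]

PROVENANCE_VALUES = ("experimental", "qsrr")


class RetentionDomainError(ValueError):
    """Inputs outside the physical/numerical domain of the retention model."""


class OracleConvergenceError(RuntimeError):
    """The migration integrator did not elute within the time horizon."""


@dataclass(frozen=True)
class GradientProgram:
    """One LC separation: gradient shape plus instrument geometry.

    Parameters
    ----------
    phi0 : float
        Strong-solvent fraction at the start of the ramp (0-1).
    delta_phi : float
        Span of the ramp; the gradient ends at ``phi0 + delta_phi``.
    t_gradient : float
        Ramp duration tG in minutes.
    t_dead : float
        Column dead (hold-up) time t0 in minutes: the transit time of an
        unretained compound.
    t_dwell : float
        Dwell time tD in minutes: delay between the solvent mixer and the
        column head (dwell volume / flow rate).
    """

    phi0: float
    delta_phi: float
    t_gradient: float
    t_dead: float
    t_dwell: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi0:
            raise ValueError(f"phi0 must be >= 0, got {self.phi0}")
        if self.delta_phi <= 0.0:
            raise ValueError(f"delta_phi must be > 0, got {self.delta_phi}")
        if self.phi0 + self.delta_phi > 1.0 + 1e-12:
            raise ValueError(
                f"phi0 + delta_phi must be <= 1, got {self.phi0 + self.delta_phi}"
            )
        if self.t_gradient <= 0.0:
            raise ValueError(f"t_gradient must be > 0, got {self.t_gradient}")
        if self.t_dead <= 0.0:
            raise ValueError(f"t_dead must be > 0, got {self.t_dead}")
        if self.t_dwell < 0.0:
            raise ValueError(f"t_dwell must be >= 0, got {self.t_dwell}")

    @property
    def ramp_end_time(self) -> float:
        """Time at which the completed ramp reaches the column outlet."""
        return self.t_dead + self.t_dwell + self.t_gradient


@dataclass(frozen=True)
class LSSParams:
    """Per-compound LSS descriptors ``(ln kw, S)`` with provenance.

    ``provenance`` records whether the pair was measured from standards
    (``"experimental"``) or predicted in silico from molecular descriptors
    (``"qsrr"``); downstream annotation applies a tighter retention-time
    tolerance to experimental parameters.
    """

    ln_kw: float
    S: float
    provenance: str = "experimental"

    def __post_init__(self) -> None:
        if not math.isfinite(self.ln_kw):
            raise ValueError(f"ln_kw must be finite, got {self.ln_kw}")
        # S = 0 is admitted as the isocratic limit of the model.
        if not (math.isfinite(self.S) and self.S >= 0.0):
            raise ValueError(f"S must be finite and >= 0, got {self.S}")
        if self.provenance not in PROVENANCE_VALUES:
            raise ValueError(
                f"provenance must be one of {PROVENANCE_VALUES}, got {self.provenance!r}"
            )


def retention_factor(params: LSSParams, phi: float) -> float:
    """Retention factor k = kw * exp(-S*phi) at solvent fraction ``phi``."""
    if not 0.0 <= phi <= 1.0:
        raise RetentionDomainError(f"phi must lie in [0, 1], got {phi}")
    return math.exp(params.ln_kw - params.S * phi)


def gradient_steepness(params: LSSParams, g: GradientProgram) -> float:
    """Intrinsic gradient steepness b = delta_phi * S * t_dead / t_gradient.

    Dimensionless; compound-specific because it scales with S.  b controls
    how strongly the moving gradient compresses the elution window.
    """
    return g.delta_phi * params.S * g.t_dead / g.t_gradient


def _initial_retention(params: LSSParams, g: GradientProgram) -> float:
    """k0 = exp(ln_kw - S*phi0): retention factor in the starting eluent."""
    return math.exp(params.ln_kw - params.S * g.phi0)


def retention_time(
    params: LSSParams, g: GradientProgram, *, oracle_dt: float = 1e-3
) -> float:
    """Predicted retention time (min) of an analyte under gradient ``g``.

    Three elution regimes are distinguished:

    a. *Pre-gradient (isocratic) elution* — the analyte leaves the column
       before the delayed gradient front catches it (``t_dead*k0 <=
       t_dwell``); then ``tR = t_dead*(1 + k0)`` with ``k0`` the retention
       factor at ``phi0``.
    b. *Elution during the ramp* — the closed form

           tR = t0*[1 + tD/t0 + (1/b)*ln(1 + b*(k0 - tD/t0))]

       with steepness ``b``; valid while tR falls before the ramp has fully
       passed the outlet.
    c. *Post-ramp elution* — the analyte is still retained when the gradient
       plateaus at ``phi0 + delta_phi``; the closed form no longer applies
       and the migration integrator (:func:`migrate_oracle`, which clamps
       the gradient at its endpoint) is used instead.

    ``b = 0`` (S = 0) reduces analytically to the isocratic ``t0*(1+k0)``.

    Raises
    ------
    RetentionDomainError
        If the logarithm argument ``1 + b*(k0 - tD/t0)`` is non-positive,
        which signals mutually inconsistent parameters.
    """
    k0 = _initial_retention(params, g)
    if g.t_dead * k0 <= g.t_dwell:
        return g.t_dead * (1.0 + k0)
    b = gradient_steepness(params, g)
    if b == 0.0:
        return g.t_dead * (1.0 + k0)
    log_arg = 1.0 + b * (k0 - g.t_dwell / g.t_dead)
    if log_arg <= 0.0:
        raise RetentionDomainError(
            "non-positive logarithm argument "
            f"1 + b*(k0 - tD/t0) = {log_arg:.6g} for params={params}, "
            "gradient inconsistent with pre-gradient elution test"
        )
    t_r = g.t_dead * (1.0 + g.t_dwell / g.t_dead + math.log(log_arg) / b)
    if t_r <= g.ramp_end_time:
        return t_r
    # Analyte would elute after the ramp has passed: integrate through the
    # end-of-gradient plateau instead.
    return migrate_oracle(params, g, dt=oracle_dt)


def retention_times(
    params_list: "list[LSSParams] | tuple[LSSParams, ...]",
    g: GradientProgram,
    *,
    oracle_dt: float = 1e-3,
) -> np.ndarray:
    """Vectorised :func:`retention_time` over a list of compounds."""
    return np.array([retention_time(p, g, oracle_dt=oracle_dt) for p in params_list])


def _phi_at(t: float, z: np.ndarray, g: GradientProgram) -> np.ndarray:
    """Local solvent fraction phi(t, z) with dwell delay and ramp clamping.

    ``z`` is the analyte position as a fraction of column length; the
    gradient front needs ``t_dwell + z*t_dead`` minutes to reach it, and
    phi is clamped to [phi0, phi0+delta_phi] (a pre-ramp hold and an
    end-of-ramp plateau).
    """
    frac = (t - g.t_dwell - z * g.t_dead) / g.t_gradient
    return g.phi0 + g.delta_phi * np.clip(frac, 0.0, 1.0)


def migrate_oracle(
    params: LSSParams,
    g: GradientProgram,
    dt: float = 1e-3,
    *,
    max_time: float = 500.0,
) -> float:
    """Retention time by direct numerical integration of analyte migration.

    Integrates ``dz/dt = u0 / (1 + k(phi(t, z)))`` (in column-length units,
    ``u0 = 1/t_dead``) with a fixed-step classical Runge-Kutta scheme until
    the analyte reaches the outlet ``z = 1``; the crossing time is refined
    by linear interpolation within the final step.  Serves as the
    independent oracle against the closed-form :func:`retention_time`, and
    as the fallback predictor for post-ramp (plateau) elution, which the
    closed form does not cover.

    Parameters
    ----------
    dt : float
        Time step in minutes; must be positive and small relative to
        ``t_dead``.
    max_time : float
        Horizon after which non-elution raises :class:`OracleConvergenceError`.
    """
    if dt <= 0.0:
        raise ValueError(f"dt must be > 0, got {dt}")
    out = _migrate_many(
        np.array([params.ln_kw]), np.array([params.S]), g, dt=dt, max_time=max_time
    )
    return float(out[0])


def _migrate_many(
    ln_kw: np.ndarray,
    S: np.ndarray,
    g: GradientProgram,
    *,
    dt: float = 1e-3,
    max_time: float = 500.0,
) -> np.ndarray:
    """RK4 migration of many analytes on a shared time grid (oracle core)."""

    def speed(t: float, z: np.ndarray) -> np.ndarray:
        phi = _phi_at(t, z, g)
        k = np.exp(ln_kw - S * phi)
        return 1.0 / (g.t_dead * (1.0 + k))

    n = ln_kw.shape[0]
    z = np.zeros(n)
    t_out = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)
    t = 0.0
    while active.any():
        if t > max_time:
            raise OracleConvergenceError(
                f"analyte(s) not eluted within max_time={max_time} min"
            )
        k1 = speed(t, z)
        k2 = speed(t + 0.5 * dt, z + 0.5 * dt * k1)
        k3 = speed(t + 0.5 * dt, z + 0.5 * dt * k2)
        k4 = speed(t + dt, z + dt * k3)
        z_new = z + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        crossed = active & (z_new >= 1.0)
        if crossed.any():
            # linear interpolation of the outlet-crossing time inside the step
            frac = (1.0 - z[crossed]) / (z_new[crossed] - z[crossed])
            t_out[crossed] = t + frac * dt
            active &= ~crossed
        z = np.where(active, z_new, z)
        t += dt
    return t_out
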