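"""Annotation of LC-MS features by exact mass and predicted retention time.

Every (feature, adduct, compound) triple is tested against two relative
tolerances:

    |q * mz + m_add - m_k| / m_k      < tol_mass
    |tR_obs - tR_pred| / tR_pred      < tol_rt

where ``m_k`` is the compound's neutral monoisotopic mass, ``m_add`` the
adduct mass excess (so neutral mass = charge*mz + mass_shift) and
``tR_pred`` the (optionally calibrated) LSS retention-time prediction.
The RT tolerance depends on the provenance of the compound's LSS
parameters: tight for experimentally measured pairs (annotation level 2+),
loose for in-silico QSRR pairs (level 2).  Both comparisons are strict.

Evaluation helpers compute the success rate (fraction of library standards
recovered by their features), the misattribution rate (fraction of
returned annotations naming the wrong compound), a tolerance sweep over
both, and annotation-multiplicity statistics with gamma-interpolated
percentiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationFit, apply_calibration
from .lss import GradientProgram, retention_time

__all__ = [
    "Adduct",
    "Feature",
    "ToleranceConfig",
    "AnnotationMatch",
    "MultiplicityStats",
    "DEFAULT_ADDUCTS",
    "PROTON_MASS",
    "WATER_MASS",
    "SODIUM_ION_MASS",
    "annotate",
    "predicted_retention_times",
    "success_rate",
    "misattribution_rate",
    "tolerance_sweep",
    "multiplicity_stats",
    "fit_gamma_percentiles",
]

# CODATA proton mass; monoisotopic H2O from 2*H(1.00782503207) + O(15.99491461956);
# sodium cation = monoisotopic Na (22.98976928) minus one electron mass.
PROTON_MASS = 1.007276466621
WATER_MASS = 18.010564684
SODIUM_ION_MASS = 22.989769282 - 0.000548579909


@dataclass(frozen=True)
class Adduct:
    """An ionisation adduct defining the m/z <-> neutral-mass relation.

    ``mass_shift`` is signed so that neutral monoisotopic mass =
    ``charge * mz + mass_shift`` (e.g. -1.007276 for [M+H]+, +17.003288
    for the water-loss adduct [M-H2O+H]+).
    """

    name: str
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")

    def neutral_mass(self, mz: float) -> float:
        return self.charge * mz + self.mass_shift

    def mz(self, neutral_mass: float) -> float:
        return (neutral_mass - self.mass_shift) / self.charge


#: the five positive-mode adducts used for steroid peak picking
DEFAULT_ADDUCTS: tuple[Adduct, ...] = (
    Adduct("[M+H]+", -PROTON_MASS),
    Adduct("[M-H2O+H]+", WATER_MASS - PROTON_MASS),
    Adduct("[M-2H2O+H]+", 2 * WATER_MASS - PROTON_MASS),
    Adduct("[M-3H2O+H]+", 3 * WATER_MASS - PROTON_MASS),
    Adduct("[M+Na]+", -SODIUM_ION_MASS),
)


@dataclass(frozen=True)
class Feature:
    """One observed LC-MS feature: an (m/z, retention time) couple.

    ``known_identity`` carries the ground-truth compound id when the
    feature comes from a standard or a simulation; it is never used by the
    annotation itself, only by the evaluation helpers.
    """

    mz: float
    rt: float
    known_identity: str | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0.0:
            raise ValueError(f"mz must be > 0, got {self.mz}")
        if self.rt < 0.0:
            raise ValueError(f"rt must be >= 0, got {self.rt}")


@dataclass(frozen=True)
class ToleranceConfig:
    """Relative matching tolerances.

    ``tol_mass`` is dimensionless (5 ppm = 5e-6).  The two RT tolerances
    correspond to the two annotation levels: 0.5% for experimentally
    measured LSS parameters, 5% for QSRR-predicted ones.
    """

    tol_mass: float = 5e-6
    tol_rt_experimental: float = 0.005
    tol_rt_qsrr: float = 0.05

    def __post_init__(self) -> None:
        for name in ("tol_mass", "tol_rt_experimental", "tol_rt_qsrr"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if self.tol_rt_experimental > self.tol_rt_qsrr:
            warnings.warn(
                "tol_rt_experimental exceeds tol_rt_qsrr; experimental "
                "parameters are normally the more reliable ones",
                stacklevel=2,
            )

    def tol_rt(self, provenance: str) -> float:
        return (
            self.tol_rt_experimental
            if provenance == "experimental"
            else self.tol_rt_qsrr
        )


@dataclass(frozen=True)
class AnnotationMatch:
    """One putative (feature, compound, adduct) identity."""

    feature_index: int
    compound_id: str
    adduct_name: str
    rel_mass_error: float
    rel_rt_error: float
    predicted_rt: float
    level: str  # "2plus" for experimental provenance, "2" for qsrr

    @property
    def combined_error(self) -> float:
        return math.hypot(self.rel_mass_error, self.rel_rt_error)


def predicted_retention_times(
    library, gradient: GradientProgram, calibration_fit: CalibrationFit | None = None
) -> np.ndarray:
    """Predicted (and optionally calibrated) tR for every library compound."""
    preds = np.array([retention_time(c.lss, gradient) for c in library.compounds])
    if calibration_fit is not None:
        preds = apply_calibration(preds, calibration_fit)
    return preds


def annotate(
    features,
    library,
    gradient: GradientProgram,
    tolerances: ToleranceConfig,
    adducts=DEFAULT_ADDUCTS,
    calibration_fit: CalibrationFit | None = None,
) -> list[list[AnnotationMatch]]:
    """Annotate every feature against the compound library.

    Returns one (possibly empty) list of :class:`AnnotationMatch` per
    feature, in feature order.  Within a feature, matches are sorted by the
    combined normalised error sqrt(rel_mass_err^2 + rel_rt_err^2)
    ascending, ties broken by compound id.
    """
    if len(library.compounds) == 0:
        raise ValueError("library is empty")
    if len(adducts) == 0:
        raise ValueError("adduct registry is empty")
    masses = np.array([c.monoisotopic_mass for c in library.compounds])
    ids = [c.compound_id for c in library.compounds]
    preds = predicted_retention_times(library, gradient, calibration_fit)
    tol_rt = np.array(
        [tolerances.tol_rt(c.lss.provenance) for c in library.compounds]
    )
    levels = [
        "2plus" if c.lss.provenance == "experimental" else "2"
        for c in library.compounds
    ]

    results: list[list[AnnotationMatch]] = []
    for i, feat in enumerate(features):
        hits: list[AnnotationMatch] = []
        rel_rt = (feat.rt - preds) / preds
        rt_ok = np.abs(rel_rt) < tol_rt
        for adduct in adducts:
            neutral = adduct.neutral_mass(feat.mz)
            rel_mass = (neutral - masses) / masses
            sel = np.flatnonzero((np.abs(rel_mass) < tolerances.tol_mass) & rt_ok)
            for k in sel:
                hits.append(
                    AnnotationMatch(
                        feature_index=i,
                        compound_id=ids[k],
                        adduct_name=adduct.name,
                        rel_mass_error=float(rel_mass[k]),
                        rel_rt_error=float(rel_rt[k]),
                        predicted_rt=float(preds[k]),
                        level=levels[k],
                    )
                )
        hits.sort(key=lambda m: (m.combined_error, m.compound_id))
        results.append(hits)
    return results


def success_rate(match_lists, features, library) -> float:
    """Fraction of library standards recovered by their own features.

    Numerator: distinct true identities for which at least one feature's
    match list contains that identity.  Denominator: distinct true
    identities (among features carrying ground truth) that are present in
    the library.  Always in [0, 1].
    """
    lib_ids = {c.compound_id for c in library.compounds}
    truths = {
        f.known_identity
        for f in features
        if f.known_identity is not None and f.known_identity in lib_ids
    }
    if not truths:
        raise ValueError("no ground-truth identities present in the library")
    recovered = set()
    for feat, matches in zip(features, match_lists):
        if feat.known_identity in truths and any(
            m.compound_id == feat.known_identity for m in matches
        ):
            recovered.add(feat.known_identity)
    return len(recovered) / len(truths)


def misattribution_rate(match_lists, features) -> float:
    """Fraction of returned annotations naming a compound other than the truth.

    Only matches of features that carry a ground-truth identity are
    counted.  Raises if there are no such annotations at all.
    """
    total = 0
    wrong = 0
    for feat, matches in zip(features, match_lists):
        if feat.known_identity is None:
            continue
        for m in matches:
            total += 1
            if m.compound_id != feat.known_identity:
                wrong += 1
    if total == 0:
        raise ValueError("no annotations over ground-truth features")
    return wrong / total


def tolerance_sweep(
    features,
    library,
    gradient: GradientProgram,
    tol_grid,
    adducts=DEFAULT_ADDUCTS,
    calibration_fit: CalibrationFit | None = None,
    tol_mass: float = 5e-6,
) -> pd.DataFrame:
    """Success and misattribution rates over a grid of RT tolerances.

    Each grid value is applied to both provenance classes (mass tolerance
    held fixed), mimicking an ROC-style sweep from tight to loose RT
    matching.  Returns a DataFrame with columns ``tol_rt``, ``n_matches``,
    ``n_annotated_features``, ``success_rate``, ``misattribution_rate``
    (NaN where no annotation exists at that tolerance).  The success
    column is checked to be non-decreasing — matches at a smaller
    tolerance are a subset of those at a larger one.
    """
    tol_grid = list(tol_grid)
    if not tol_grid:
        raise ValueError("tol_grid is empty")
    if any(b <= a for a, b in zip(tol_grid, tol_grid[1:])):
        raise ValueError("tol_grid must be strictly increasing")
    rows = []
    for tol in tol_grid:
        tc = ToleranceConfig(
            tol_mass=tol_mass, tol_rt_experimental=tol, tol_rt_qsrr=tol
        )
        match_lists = annotate(
            features, library, gradient, tc, adducts, calibration_fit
        )
        n_matches = sum(len(m) for m in match_lists)
        try:
            succ = success_rate(match_lists, features, library)
        except ValueError:
            succ = math.nan
        try:
            mis = misattribution_rate(match_lists, features)
        except ValueError:
            mis = math.nan
        rows.append(
            {
                "tol_rt": tol,
                "n_matches": n_matches,
                "n_annotated_features": sum(1 for m in match_lists if m),
                "success_rate": succ,
                "misattribution_rate": mis,
            }
        )
    table = pd.DataFrame(rows)
    succ = table["success_rate"].to_numpy()
    finite = np.isfinite(succ)
    if np.any(np.diff(succ[finite]) < 0):  # pragma: no cover - invariant guard
        raise AssertionError("success rate decreased with increasing tolerance")
    return table


@dataclass(frozen=True)
class MultiplicityStats:
    """Annotations-per-annotated-feature summary with gamma percentiles."""

    mean: float
    p50: float
    p75: float
    p90: float
    gamma_shape: float
    gamma_scale: float
    n_annotated: int


def multiplicity_stats(match_lists) -> MultiplicityStats:
    """Mean and gamma-interpolated percentiles of annotation multiplicity.

    Counts are taken per *annotated* feature only (features with empty
    match lists are excluded).  A gamma distribution is fitted by maximum
    likelihood (location fixed at zero, method-of-moments starting values)
    and its 50/75/90% quantiles reported; the gamma family covers most
    non-negative unimodal shapes while staying analytically tractable.
    Degenerate all-equal counts short-circuit to that common value.
    """
    counts = np.array([len(m) for m in match_lists if m], dtype=float)
    if counts.size == 0:
        raise ValueError("no annotated features")
    mean = float(counts.mean())
    if np.ptp(counts) == 0.0:
        v = float(counts[0])
        return MultiplicityStats(mean, v, v, v, math.nan, math.nan, counts.size)
    shape, scale, (p50, p75, p90) = fit_gamma_percentiles(counts)
    return MultiplicityStats(
        mean, p50, p75, p90, shape, scale, counts.size
    )


def fit_gamma_percentiles(
    values, probs=(0.50, 0.75, 0.90)
) -> tuple[float, float, tuple[float, ...]]:
    """Gamma MLE (location fixed at 0) and interpolated percentiles.

    Starting values come from the method of moments.  Returns
    ``(shape, scale, percentiles)``.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    var = values.var()
    if var == 0.0:
        raise ValueError("degenerate sample: zero variance")
    shape, _, scale = stats.gamma.fit(
        values, mean**2 / var, floc=0.0, scale=var / mean
    )
    pct = stats.gamma.ppf(probs, shape, scale=scale)
    return float(shape), float(scale), tuple(float(p) for p in pct)
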