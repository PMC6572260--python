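"""Synthetic compound libraries, features and perturbed instruments.

Every stage of the pipeline is testable without external data: this
module generates steroid-like compound libraries with known (ln kw, S),
LC-MS feature lists derived from them with controllable retention-time
noise and guaranteed-unmatchable decoys, and perturbed copies of a
gradient program emulating mis-specified instrument geometry.

The default scenario mirrors the separation the annotation engine was
characterised on: a 2% -> 100% acetonitrile ramp over 14 min on a column
with 0.8 min dead time and 0.75 min dwell time, compounds in a 250-500 Da
steroid mass window with ln_kw ~ U(5, 11) and S ~ U(15, 40) (initial
retention k0 well above 10^2 for all draws), and a fifth of the library
grouped into isomer clusters sharing an exact mass — the hard case the
retention dimension exists to resolve.

All randomness flows through :func:`numpy.random.default_rng` (PCG64);
fixed seed implies bit-identical output across platforms.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .annotation import DEFAULT_ADDUCTS, Adduct, Feature
from .calibration import PerturbationSpec
from .io import CompoundRecord, LibraryManifest
from .lss import GradientProgram, LSSParams, retention_time

__all__ = [
    "DEFAULT_GRADIENT",
    "SyntheticScenario",
    "gen_library",
    "gen_features",
    "perturb_gradient",
    "true_retention_times",
]

#: the characterisation separation: 2->100% B over 14 min, t0=0.8, tD=0.75 min
DEFAULT_GRADIENT = GradientProgram(
    phi0=0.02, delta_phi=0.98, t_gradient=14.0, t_dead=0.8, t_dwell=0.75
)

#: decoy neutral masses live here, disjoint from the compound mass window,
#: so no decoy can mass-match any compound under any registered adduct
_DECOY_MASS_WINDOW = (600.0, 900.0)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one simulated study.

    ``rt_noise_sd`` (min) is the measurement noise on feature retention
    times; 0.005 min reflects the run-to-run reproducibility of a modern
    UHPLC separation.  ``isomer_fraction`` of compounds are placed in
    clusters of 2-3 sharing an identical exact mass (distinct LSS
    parameters), the situation that motivates retention-based annotation.
    ``feature_adducts`` are the adduct forms under which each compound is
    observed; decoy features mimic unrelated sample background.
    """

    seed: int = 0
    n_compounds: int = 70
    ln_kw_range: tuple[float, float] = (5.0, 11.0)
    S_range: tuple[float, float] = (15.0, 40.0)
    mass_range: tuple[float, float] = (250.0, 500.0)
    gradient: GradientProgram = DEFAULT_GRADIENT
    perturbation: PerturbationSpec = PerturbationSpec()
    rt_noise_sd: float = 0.005
    n_decoys: int = 0
    isomer_fraction: float = 0.2
    experimental_fraction: float = 1.0
    feature_adducts: tuple[Adduct, ...] = (DEFAULT_ADDUCTS[0],)

    def __post_init__(self) -> None:
        for name in ("ln_kw_range", "S_range", "mass_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be non-degenerate, got ({lo}, {hi})")
        if self.rt_noise_sd < 0.0:
            raise ValueError("rt_noise_sd must be >= 0")
        if not 0.0 <= self.isomer_fraction <= 1.0:
            raise ValueError("isomer_fraction must be in [0, 1]")
        if not 0.0 <= self.experimental_fraction <= 1.0:
            raise ValueError("experimental_fraction must be in [0, 1]")


def _rng(scenario: SyntheticScenario, stream: str) -> np.random.Generator:
    """Independent named substream so library and features decouple.

    The stream key is a CRC32 of the stream name (stable across processes,
    unlike the builtin ``hash``).
    """
    key = zlib.crc32(stream.encode("ascii"))
    ss = np.random.SeedSequence(scenario.seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def gen_library(scenario: SyntheticScenario) -> LibraryManifest:
    """Generate a compound library with seeded isomer clusters.

    ln_kw and S are uniform over the scenario ranges; masses are uniform
    over the steroid-like window, with ``isomer_fraction`` of the
    compounds grouped into clusters of 2-3 that share one exact mass.
    Provenance is experimental for the first ``experimental_fraction`` of
    compounds (deterministic split) and qsrr for the rest.
    """
    n = scenario.n_compounds
    if n == 0:
        return LibraryManifest(compounds=())
    rng = _rng(scenario, "library")
    ln_kw = rng.uniform(*scenario.ln_kw_range, size=n)
    S = rng.uniform(*scenario.S_range, size=n)
    masses = rng.uniform(*scenario.mass_range, size=n)

    # group ~isomer_fraction of compounds into clusters of 2-3 sharing a mass
    n_clustered = int(round(scenario.isomer_fraction * n))
    i = 0
    while i < n_clustered - 1:
        size = int(rng.integers(2, 4))
        size = min(size, n_clustered - i)
        if size >= 2:
            masses[i : i + size] = masses[i]
        i += size

    n_exp = int(round(scenario.experimental_fraction * n))
    compounds = []
    for j in range(n):
        provenance = "experimental" if j < n_exp else "qsrr"
        compounds.append(
            CompoundRecord(
                compound_id=f"CPD{j:04d}",
                name=f"synthetic steroid {j}",
                monoisotopic_mass=float(masses[j]),
                lss=LSSParams(
                    ln_kw=float(ln_kw[j]), S=float(S[j]), provenance=provenance
                ),
            )
        )
    return LibraryManifest(compounds=tuple(compounds))


def true_retention_times(
    library: LibraryManifest, gradient: GradientProgram
) -> np.ndarray:
    """Noise-free retention times of every library compound (ground truth)."""
    return np.array([retention_time(c.lss, gradient) for c in library.compounds])


def gen_features(
    library: LibraryManifest, scenario: SyntheticScenario
) -> list[Feature]:
    """Generate an LC-MS feature list with ground truth from a library.

    One feature per (compound, feature adduct): m/z back-computed from the
    neutral mass through the adduct relation, retention time equal to the
    true model prediction plus Gaussian noise.  ``n_decoys`` extra
    features carry neutral masses in a window disjoint from the compound
    mass range — unmatchable by construction rather than by rejection
    sampling — and uniform retention times across the elution window.
    """
    rng = _rng(scenario, "features")
    g = scenario.gradient
    truths = true_retention_times(library, g)
    features = []
    for compound, t_true in zip(library.compounds, truths):
        for adduct in scenario.feature_adducts:
            rt = float(t_true + rng.normal(0.0, scenario.rt_noise_sd)) \
                if scenario.rt_noise_sd > 0 else float(t_true)
            features.append(
                Feature(
                    mz=adduct.mz(compound.monoisotopic_mass),
                    rt=max(rt, 0.0),
                    known_identity=compound.compound_id,
                )
            )
    proton = DEFAULT_ADDUCTS[0]
    for _ in range(scenario.n_decoys):
        mass = rng.uniform(*_DECOY_MASS_WINDOW)
        rt = rng.uniform(g.t_dead, g.ramp_end_time)
        features.append(Feature(mz=proton.mz(mass), rt=float(rt), known_identity=None))
    return features


def perturb_gradient(g: GradientProgram, p: PerturbationSpec) -> GradientProgram:
    """Apply relative instrument-parameter perturbations to a gradient.

    t0 and tD are scaled by (1 + rel); the steepness perturbation rel_db
    is realised by scaling the ramp duration by 1/(1 + rel_db), since b is
    proportional to 1/t_gradient.  Raises if the perturbed program
    violates the gradient invariants.
    """
    return replace(
        g,
        t_dead=g.t_dead * (1.0 + p.rel_dt0),
        t_dwell=g.t_dwell * (1.0 + p.rel_dtD),
        t_gradient=g.t_gradient / (1.0 + p.rel_db),
    )
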