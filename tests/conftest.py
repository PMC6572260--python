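import numpy as np
import pytest

from lssannot import (
    DEFAULT_GRADIENT,
    GradientProgram,
    LSSParams,
    SyntheticScenario,
    gen_features,
    gen_library,
)


@pytest.fixture(scope="session")
def gradient() -> GradientProgram:
    """The characterisation gradient: 2->100% B / 14 min, t0=0.8, tD=0.75."""
    return DEFAULT_GRADIENT


@pytest.fixture(scope="session")
def random_params():
    """100 seeded LSS parameter draws over the steroid-like ranges."""
    rng = np.random.default_rng(1234)
    ln_kw = rng.uniform(5.0, 11.0, size=100)
    S = rng.uniform(15.0, 40.0, size=100)
    return [LSSParams(ln_kw=float(a), S=float(s)) for a, s in zip(ln_kw, S)]


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """Noiseless closed-loop scenario: 30 compounds, no decoys."""
    return SyntheticScenario(
        seed=7, n_compounds=30, rt_noise_sd=0.0, n_decoys=0, isomer_fraction=0.0
    )


@pytest.fixture(scope="session")
def small_library(small_scenario):
    return gen_library(small_scenario)


@pytest.fixture(scope="session")
def small_features(small_library, small_scenario):
    return gen_features(small_library, small_scenario)


@pytest.fixture(scope="session")
def brute_force_reference():
    """Exhaustive (feature, adduct, compound) triple-loop oracle.

    Returns the set of (feature_index, compound_id, adduct_name) keys that
    satisfy both relative tolerances, computed without any of the vectorised
    shortcuts of the production path.
    """

    def _brute(features, library, gradient, tolerances, adducts, preds):
        hits = set()
        for i, feat in enumerate(features):
            for adduct in adducts:
                neutral = adduct.charge * feat.mz + adduct.mass_shift
                for k, c in enumerate(library.compounds):
                    mass_ok = (
                        abs(neutral - c.monoisotopic_mass) / c.monoisotopic_mass
                        < tolerances.tol_mass
                    )
                    tol_rt = tolerances.tol_rt(c.lss.provenance)
                    rt_ok = abs(feat.rt - preds[k]) / preds[k] < tol_rt
                    if mass_ok and rt_ok:
                        hits.add((i, c.compound_id, adduct.name))
        return hits

    return _brute
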