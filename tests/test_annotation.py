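"""Feature annotation: adduct mass matching, rates, sweep, multiplicity."""

import numpy as np
import pytest

from lssannot import (
    DEFAULT_ADDUCTS,
    Adduct,
    AnnotationMatch,
    CompoundRecord,
    Feature,
    LSSParams,
    LibraryManifest,
    SyntheticScenario,
    ToleranceConfig,
    annotate,
    fit_gamma_percentiles,
    gen_features,
    gen_library,
    misattribution_rate,
    multiplicity_stats,
    predicted_retention_times,
    retention_time,
    success_rate,
    tolerance_sweep,
)

ADDUCT_BY_NAME = {a.name: a for a in DEFAULT_ADDUCTS}


def _match_key(m: AnnotationMatch):
    return (m.feature_index, m.compound_id, m.adduct_name)


class TestAdductRegistry:
    def test_shifts_against_independent_isotope_table(self):
        """Registry mass shifts agree with pyteomics' NIST-derived tables."""
        from pyteomics import mass as pmass

        proton = pmass.nist_mass["H+"][0][0]
        water = pmass.calculate_mass(formula="H2O")
        sodium_ion = pmass.nist_mass["Na"][0][0] - pmass.nist_mass["e*"][0][0]
        expected = {
            "[M+H]+": -proton,
            "[M-H2O+H]+": water - proton,
            "[M-2H2O+H]+": 2 * water - proton,
            "[M-3H2O+H]+": 3 * water - proton,
            "[M+Na]+": -sodium_ion,
        }
        for adduct in DEFAULT_ADDUCTS:
            assert adduct.mass_shift == pytest.approx(
                expected[adduct.name], abs=1e-6
            ), adduct.name

    def test_neutral_mass_mz_round_trip(self):
        for adduct in DEFAULT_ADDUCTS:
            assert adduct.neutral_mass(adduct.mz(300.0)) == pytest.approx(300.0)

    def test_charge_validation(self):
        with pytest.raises(ValueError):
            Adduct("bad", 0.0, charge=0)


def _one_compound_library(gradient):
    return LibraryManifest(
        compounds=(
            CompoundRecord(
                compound_id="C1",
                name="one",
                monoisotopic_mass=302.2246,
                lss=LSSParams(ln_kw=8.0, S=25.0),
            ),
        )
    )


class TestAnnotate:
    def test_empty_feature_list(self, gradient):
        lib = _one_compound_library(gradient)
        assert annotate([], lib, gradient, ToleranceConfig()) == []

    def test_exact_protonated_hit(self, gradient):
        lib = _one_compound_library(gradient)
        t_star = retention_time(lib.compounds[0].lss, gradient)
        feat = Feature(mz=302.2246 + 1.007276, rt=t_star)
        (matches,) = annotate([feat], lib, gradient, ToleranceConfig())
        assert len(matches) == 1
        m = matches[0]
        assert m.compound_id == "C1"
        assert m.adduct_name == "[M+H]+"
        assert m.level == "2plus"
        assert abs(m.rel_mass_error) < 1e-6
        assert m.rel_rt_error == 0.0

    def test_qsrr_provenance_gives_level_2(self, gradient):
        lib = LibraryManifest(
            compounds=(
                CompoundRecord(
                    "Q1", "q", 302.2246,
                    LSSParams(ln_kw=8.0, S=25.0, provenance="qsrr"),
                ),
            )
        )
        t_star = retention_time(lib.compounds[0].lss, gradient)
        feat = Feature(mz=302.2246 + 1.007276, rt=t_star)
        (matches,) = annotate([feat], lib, gradient, ToleranceConfig())
        assert matches[0].level == "2"

    def test_strict_tolerance_boundary_excluded(self, gradient):
        # a relative mass error exactly equal to the tolerance is NOT a match
        lib = LibraryManifest(
            compounds=(
                CompoundRecord("C1", "one", 256.0, LSSParams(ln_kw=8.0, S=25.0)),
            )
        )
        t_star = retention_time(lib.compounds[0].lss, gradient)
        neutral_adduct = Adduct("[M]", 0.0)  # mass_shift 0 keeps arithmetic exact
        tc = ToleranceConfig(tol_mass=0.25, tol_rt_experimental=0.5, tol_rt_qsrr=0.5)
        at_boundary = Feature(mz=320.0, rt=t_star)  # rel mass error = 0.25 exactly
        inside = Feature(mz=319.0, rt=t_star)
        results = annotate(
            [at_boundary, inside], lib, gradient, tc, adducts=(neutral_adduct,)
        )
        assert results[0] == []
        assert len(results[1]) == 1

    def test_matches_sorted_by_combined_error(self, gradient):
        scenario = SyntheticScenario(
            seed=3, n_compounds=40, rt_noise_sd=0.01, isomer_fraction=0.5,
            feature_adducts=DEFAULT_ADDUCTS,
        )
        lib = gen_library(scenario)
        feats = gen_features(lib, scenario)
        results = annotate(
            feats, lib, gradient,
            ToleranceConfig(tol_mass=2e-3, tol_rt_experimental=0.2, tol_rt_qsrr=0.2),
        )
        for matches in results:
            errs = [m.combined_error for m in matches]
            assert errs == sorted(errs)

    def test_equals_brute_force_triple_loop(self, gradient, brute_force_reference):
        """Exact set equality with the exhaustive reference on a 50x5x200 fixture."""
        scenario = SyntheticScenario(
            seed=77, n_compounds=50, rt_noise_sd=0.01, n_decoys=0,
            feature_adducts=DEFAULT_ADDUCTS[:4],
        )
        lib = gen_library(scenario)
        feats = gen_features(lib, scenario)  # 50 compounds x 4 adducts = 200
        assert len(feats) == 200
        tc = ToleranceConfig(tol_mass=5e-6, tol_rt_experimental=0.01, tol_rt_qsrr=0.05)
        results = annotate(feats, lib, gradient, tc, DEFAULT_ADDUCTS)
        got = {_match_key(m) for matches in results for m in matches}
        preds = predicted_retention_times(lib, gradient)
        expected = brute_force_reference(
            feats, lib, gradient, tc, DEFAULT_ADDUCTS, preds
        )
        assert got == expected
        assert len(got) > 0

    def test_decoys_unmatched_at_default_tolerances(self, gradient):
        scenario = SyntheticScenario(seed=5, n_compounds=20, n_decoys=40)
        lib = gen_library(scenario)
        feats = gen_features(lib, scenario)
        results = annotate(feats, lib, gradient, ToleranceConfig())
        for feat, matches in zip(feats, results):
            if feat.known_identity is None:
                assert matches == []

    def test_empty_library_rejected(self, gradient):
        with pytest.raises(ValueError):
            annotate([], LibraryManifest(compounds=()), gradient, ToleranceConfig())


def _fake_matches(pairs):
    """Build match lists from (feature_index, compound_id) pairs."""
    out = {}
    for i, cid in pairs:
        out.setdefault(i, []).append(
            AnnotationMatch(i, cid, "[M+H]+", 0.0, 0.0, 5.0, "2plus")
        )
    return out


def _features_with_truth(truths):
    return [Feature(mz=300.0, rt=5.0, known_identity=t) for t in truths]


def _library_of(ids):
    return LibraryManifest(
        compounds=tuple(
            CompoundRecord(cid, cid, 300.0, LSSParams(8.0, 25.0)) for cid in ids
        )
    )


class TestRates:
    def test_all_standards_recovered(self):
        feats = _features_with_truth(["A", "B", "C", "D", "E"])
        lib = _library_of(["A", "B", "C", "D", "E"])
        by_index = _fake_matches([(i, t) for i, t in enumerate("ABCDE")])
        lists = [by_index.get(i, []) for i in range(5)]
        assert success_rate(lists, feats, lib) == 1.0
        assert misattribution_rate(lists, feats) == 0.0

    def test_partial_recovery_fraction(self):
        ids = [f"C{i}" for i in range(10)]
        feats = _features_with_truth(ids)
        lib = _library_of(ids)
        by_index = _fake_matches([(i, ids[i]) for i in range(8)])
        lists = [by_index.get(i, []) for i in range(10)]
        assert success_rate(lists, feats, lib) == pytest.approx(0.8)

    def test_no_matches_gives_zero_success(self):
        feats = _features_with_truth(["A", "B"])
        lib = _library_of(["A", "B"])
        assert success_rate([[], []], feats, lib) == 0.0

    def test_no_truth_in_library_is_an_error(self):
        feats = _features_with_truth(["X"])
        lib = _library_of(["A"])
        with pytest.raises(ValueError):
            success_rate([[]], feats, lib)

    def test_misattribution_third(self):
        feats = _features_with_truth(["A", "B", "C"])
        pairs = (
            [(0, "A")] * 1 + [(0, "Z")] * 2  # 2 wrong on feature 0
            + [(1, "B")] * 4 + [(1, "Y")] * 2  # 2 wrong on feature 1
            + [(2, "C")] * 3
        )
        by_index = _fake_matches(pairs)
        lists = [by_index.get(i, []) for i in range(3)]
        assert misattribution_rate(lists, feats) == pytest.approx(4 / 12)

    def test_truth_absent_from_library_all_misattributed(self):
        feats = _features_with_truth(["MISSING"])
        by_index = _fake_matches([(0, "A"), (0, "B")])
        assert misattribution_rate([by_index[0]], feats) == 1.0

    def test_zero_annotations_is_an_error(self):
        feats = _features_with_truth(["A"])
        with pytest.raises(ValueError):
            misattribution_rate([[]], feats)


@pytest.fixture(scope="module")
def noisy_fixture():
    scenario = SyntheticScenario(
        seed=21, n_compounds=40, rt_noise_sd=0.02, n_decoys=20,
        isomer_fraction=0.3,
    )
    lib = gen_library(scenario)
    feats = gen_features(lib, scenario)
    return feats, lib


class TestToleranceSweep:
    def test_success_monotone_over_grid(self, noisy_fixture, gradient):
        feats, lib = noisy_fixture
        table = tolerance_sweep(
            feats, lib, gradient, [0.005, 0.01, 0.05, 0.10, 0.15]
        )
        succ = table["success_rate"].to_numpy()
        assert np.all(np.diff(succ[np.isfinite(succ)]) >= 0)
        assert np.all(np.diff(table["n_matches"].to_numpy()) >= 0)

    def test_sweep_rows_match_direct_recount(self, noisy_fixture, gradient):
        feats, lib = noisy_fixture
        grid = [0.01, 0.05]
        table = tolerance_sweep(feats, lib, gradient, grid)
        for tol, row in zip(grid, table.itertuples()):
            tc = ToleranceConfig(
                tol_mass=5e-6, tol_rt_experimental=tol, tol_rt_qsrr=tol
            )
            lists = annotate(feats, lib, gradient, tc)
            assert row.n_matches == sum(len(m) for m in lists)
            assert row.success_rate == pytest.approx(
                success_rate(lists, feats, lib)
            )

    def test_vacuous_rt_tolerance_reduces_to_mass_matching(self, gradient):
        scenario = SyntheticScenario(seed=13, n_compounds=25, rt_noise_sd=0.0)
        lib = gen_library(scenario)
        feats = gen_features(lib, scenario)
        table = tolerance_sweep(feats, lib, gradient, [1e3])
        assert table["success_rate"].iloc[0] == 1.0  # every mass self-matches

    def test_grid_must_be_increasing(self, noisy_fixture, gradient):
        feats, lib = noisy_fixture
        with pytest.raises(ValueError):
            tolerance_sweep(feats, lib, gradient, [0.05, 0.01])

    def test_rates_bounded(self, noisy_fixture, gradient):
        feats, lib = noisy_fixture
        table = tolerance_sweep(feats, lib, gradient, [0.005, 0.05, 0.15])
        for col in ("success_rate", "misattribution_rate"):
            vals = table[col].to_numpy()
            vals = vals[np.isfinite(vals)]
            assert np.all((vals >= 0) & (vals <= 1))


class TestMultiplicity:
    def test_all_single_annotations_degenerate(self):
        lists = [[object()] for _ in range(10)] + [[]]
        stats = multiplicity_stats(lists)
        assert stats.mean == 1.0
        assert stats.p50 == stats.p75 == stats.p90 == 1.0
        assert stats.n_annotated == 10

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            multiplicity_stats([[], []])

    def test_gamma_parameter_recovery(self):
        """Shape/scale recovered within 5% from 1e4 seeded gamma draws."""
        rng = np.random.default_rng(8)
        draws = rng.gamma(shape=2.0, scale=1.5, size=10_000)
        shape, scale, _ = fit_gamma_percentiles(draws)
        assert shape == pytest.approx(2.0, rel=0.05)
        assert scale == pytest.approx(1.5, rel=0.05)

    def test_percentiles_come_from_fitted_gamma(self):
        from scipy import stats as sps

        rng = np.random.default_rng(9)
        draws = rng.gamma(shape=3.0, scale=0.8, size=2_000)
        shape, scale, (p50, p75, p90) = fit_gamma_percentiles(draws)
        assert p50 == pytest.approx(sps.gamma.ppf(0.5, shape, scale=scale))
        assert p50 < p75 < p90

    def test_unique_identities_at_tight_tolerance(self, gradient):
        """Well-separated compounds annotate with multiplicity exactly 1."""
        scenario = SyntheticScenario(
            seed=31, n_compounds=30, rt_noise_sd=0.0, isomer_fraction=0.0
        )
        lib = gen_library(scenario)
        preds = predicted_retention_times(lib, gradient)
        masses = np.array([c.monoisotopic_mass for c in lib.compounds])
        # premise: pairwise separation >1% in rt or >2*tol_mass in mass
        for i in range(len(lib.compounds)):
            for j in range(i + 1, len(lib.compounds)):
                rt_sep = abs(preds[i] - preds[j]) / min(preds[i], preds[j])
                m_sep = abs(masses[i] - masses[j]) / min(masses[i], masses[j])
                assert rt_sep > 0.01 or m_sep > 1e-5
        feats = gen_features(lib, scenario)
        lists = annotate(
            feats, lib, gradient,
            ToleranceConfig(tol_rt_experimental=0.005, tol_rt_qsrr=0.005),
        )
        stats = multiplicity_stats(lists)
        assert stats.mean == 1.0
        assert stats.p90 == 1.0
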