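import numpy as np
import pytest

from eimseval import similarity as sim
from eimseval.spectral_io import Peak, SpectrumLibrary
from eimseval.synth import ClassSpec, PerturbationConfig, generate_reference_spectrum, perturb_spectrum

from conftest import brute_force_score, make_spectrum, random_spectrum

W = sim.DEFAULT_WEIGHTS


class TestAlignUnion:
    def test_disjoint_spectra(self):
        a = make_spectrum([(83, 100)])
        b = make_spectrum([(126, 100)])
        mz, ia, ib = sim.align_union(a, b)
        assert mz.tolist() == [83.0, 126.0]
        assert ia.tolist() == [100.0, 0.0]
        assert ib.tolist() == [0.0, 100.0]

    def test_identical_spectra_pair_componentwise(self):
        s = make_spectrum([(43, 10), (83, 30), (126, 100)])
        _, ia, ib = sim.align_union(s, s)
        assert ia.tolist() == ib.tolist() == [10.0, 30.0, 100.0]

    def test_partial_overlap(self, two_peak_pair):
        a, b = two_peak_pair
        mz, ia, ib = sim.align_union(a, b)
        assert mz.tolist() == [50.0, 100.0]
        assert ia.tolist() == [100.0, 50.0]
        assert ib.tolist() == [50.0, 100.0]


class TestScores:
    def test_identical_spectra_score_exactly_1000(self):
        s = make_spectrum([(43, 10), (83, 30), (126, 100)])
        assert sim.cosine_score(s, s) == 1000.0
        assert sim.wdot_score(s, s) == 1000.0

    def test_disjoint_spectra_score_zero(self):
        a = make_spectrum([(83, 100)])
        b = make_spectrum([(126, 100)])
        assert sim.cosine_score(a, b) == 0.0
        assert sim.wdot_score(a, b) == 0.0

    def test_worked_cosine_example(self, two_peak_pair):
        # 10000 / 12500 * 1000
        assert sim.cosine_score(*two_peak_pair) == pytest.approx(800.0, rel=1e-12)

    def test_worked_wdot_example(self, two_peak_pair):
        a, b = two_peak_pair
        expected = brute_force_score(a, b)  # mass weighting dominates the low-mz disagreement
        assert expected == pytest.approx(994.5, abs=0.05)
        assert sim.wdot_score(a, b) == pytest.approx(expected, rel=1e-12)

    def test_single_peak_same_mz_any_intensities(self):
        a = make_spectrum([(83, 100)])
        b = make_spectrum([(83, 37)])
        assert sim.wdot_score(a, b) == 1000.0

    def test_weighted_intensity(self):
        assert sim.weighted_intensity(Peak(1, 1)) == 1.0
        assert sim.weighted_intensity(Peak(50.0, 0.0)) == 0.0
        assert sim.weighted_intensity(Peak(100, 100)) == pytest.approx(
            100**0.6 * 100**3, rel=1e-12
        )

    def test_empty_spectrum_rejected(self):
        a = make_spectrum([(83, 100)])
        zero = a.with_peaks((Peak(83.0, 0.0),))
        with pytest.raises(ValueError):
            sim.wdot_score(a, zero)


class TestProperties:
    def test_symmetry_bounds_and_scale_invariance(self):
        rng = np.random.default_rng(202)
        for i in range(50):
            a = random_spectrum(rng, sid="a")
            b = random_spectrum(rng, sid="b")
            for fn in (sim.cosine_score, sim.wdot_score):
                s_ab, s_ba = fn(a, b), fn(b, a)
                assert s_ab == pytest.approx(s_ba, abs=1e-9)
                assert 0.0 <= s_ab <= 1000.0
            half = b.with_peaks(tuple(Peak(p.mz, p.intensity / 3) for p in b.peaks))
            assert sim.wdot_score(a, half) == pytest.approx(sim.wdot_score(a, b), rel=1e-12)

    def test_brute_force_oracle_agreement_small(self):
        rng = np.random.default_rng(77)
        for i in range(100):
            a = random_spectrum(rng, sid="a")
            b = random_spectrum(rng, sid="b")
            assert sim.wdot_score(a, b) == pytest.approx(
                brute_force_score(a, b), rel=1e-9, abs=1e-9
            )
            assert sim.cosine_score(a, b) == pytest.approx(
                brute_force_score(a, b, weighted=False), rel=1e-9, abs=1e-9
            )

    def test_median_score_degrades_monotonically_with_dropout(self):
        spec = ClassSpec("Pyrimidines", loss_profile={"HCN": 0.6, "CO": 0.4})
        medians = []
        for dropout in (0.0, 0.3, 0.6, 0.9):
            scores = []
            for rep in range(100):
                ref = generate_reference_spectrum(spec, 1000 + rep, mol_id="M")
                pert = perturb_spectrum(
                    ref, PerturbationConfig(dropout_prob=dropout, seed=5000 + rep)
                )
                scores.append(sim.wdot_score(pert, ref))
            medians.append(float(np.median(scores)))
        assert medians == sorted(medians, reverse=True)


class TestBands:
    @pytest.mark.parametrize(
        "score,label",
        [(810, "excellent"), (801, "excellent"), (800, "good"), (650, "good"),
         (601, "good"), (600, "fair"), (500, "fair"), (401, "fair"),
         (400, "poor"), (0, "poor"), (1000, "excellent")],
    )
    def test_fig_bands_boundaries(self, score, label):
        assert sim.score_band(score) == label

    def test_classic_scheme(self):
        assert sim.score_band(851, scheme="classic") == "good"
        assert sim.score_band(850, scheme="classic") == "moderate"
        assert sim.score_band(599, scheme="classic") == "poor"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sim.score_band(1001)


class TestMatrix:
    def test_self_comparison_diagonal_is_1000(self, small_library):
        m = sim.similarity_matrix(small_library, small_library)
        assert np.allclose(np.diag(m.to_numpy()), 1000.0)

    def test_swapping_arguments_transposes(self, small_library):
        rng = np.random.default_rng(9)
        other = SpectrumLibrary([random_spectrum(rng, sid=f"r{i}") for i in range(4)])
        m = sim.similarity_matrix(small_library, other)
        mt = sim.similarity_matrix(other, small_library)
        assert np.allclose(m.to_numpy(), mt.to_numpy().T)

    def test_entries_equal_pairwise_scores(self, small_library):
        m = sim.similarity_matrix(small_library, small_library, metric="wdot")
        for a in small_library:
            for b in small_library:
                assert m.loc[a.id, b.id] == pytest.approx(
                    brute_force_score(a, b), rel=1e-9
                )
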