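import numpy as np
import pytest

from eimseval import molion as mi
from eimseval import synth
from eimseval.spectral_io import write_msp

from conftest import make_spectrum

SPEC = synth.ClassSpec("Pyrimidines", loss_profile={"HCN": 0.6, "CO": 0.4})


class TestReferenceGenerator:
    def test_fixed_seed_is_deterministic(self):
        assert synth.generate_reference_spectrum(SPEC, 42) == synth.generate_reference_spectrum(SPEC, 42)

    def test_molion_always_base_peak_when_base_prob_one(self):
        spec = synth.ClassSpec("X", molion_base_prob=1.0)
        for seed in range(10):
            s = synth.generate_reference_spectrum(spec, seed)
            assert s.peak_at(float(s.nominal_mw)).intensity == 100.0

    def test_controlled_molion_survival(self):
        spec = synth.ClassSpec("X", molion_base_prob=0.0, molion_survival=(40.0, 60.0))
        for seed in range(10):
            s = synth.generate_reference_spectrum(spec, seed)
            assert 40.0 <= s.peak_at(float(s.nominal_mw)).intensity <= 60.0
            assert s.base_peak.intensity == 100.0

    def test_certain_loss_emission(self):
        spec = synth.ClassSpec("X", loss_profile={"HCN": 1.0})
        for seed in range(10):
            s = synth.generate_reference_spectrum(spec, seed)
            assert s.peak_at(float(s.nominal_mw - 27)) is not None

    def test_spectrum_is_normalized_with_mw_range_respected(self):
        s = synth.generate_reference_spectrum(SPEC, 3)
        assert s.base_peak.intensity == 100.0
        assert SPEC.mw_range[0] <= s.nominal_mw <= SPEC.mw_range[1]
        assert max(s.mz) <= s.nominal_mw


class TestPerturbation:
    def test_all_zero_config_is_identity(self):
        s = synth.generate_reference_spectrum(SPEC, 7)
        assert synth.perturb_spectrum(s, synth.PerturbationConfig(seed=1)) == s

    def test_full_dropout_leaves_only_molecular_ion(self):
        s = make_spectrum(
            [(40 + 5 * i, 10 + i) for i in range(10)] + [(126, 50)], mw=126
        )
        out = synth.perturb_spectrum(s, synth.PerturbationConfig(dropout_prob=1.0, seed=0))
        assert out.mz == (126.0,)
        assert out.intensities == (100.0,)

    def test_empirical_dropout_matches_configured_rate(self):
        d = 0.35
        cfg = synth.PerturbationConfig(dropout_prob=d)
        kept = total = 0
        for seed in range(500):
            s = synth.generate_reference_spectrum(SPEC, seed)
            out = synth.perturb_spectrum(
                s, synth.PerturbationConfig(dropout_prob=d, seed=10_000 + seed)
            )
            frags = [p.mz for p in s.peaks if p.mz != float(s.nominal_mw) and p.intensity >= 2]
            total += len(frags)
            kept += sum(1 for mz in frags if out.peak_at(mz) is not None)
        se = (d * (1 - d) / total) ** 0.5
        assert abs((1 - kept / total) - d) < 3 * se

    def test_empirical_extra_peak_rate(self):
        rate = 3.0
        cfg_total = 0
        for seed in range(300):
            s = synth.generate_reference_spectrum(SPEC, seed)
            out = synth.perturb_spectrum(
                s, synth.PerturbationConfig(extra_peak_rate=rate, seed=20_000 + seed)
            )
            cfg_total += len(out.peaks) - len(s.peaks)
        mean = cfg_total / 300
        se = (rate / 300) ** 0.5
        assert abs(mean - rate) < 3 * se

    def test_molion_never_dropped(self):
        s = synth.generate_reference_spectrum(SPEC, 11)
        out = synth.perturb_spectrum(
            s, synth.PerturbationConfig(dropout_prob=0.9, seed=3)
        )
        assert out.peak_at(float(s.nominal_mw)) is not None


class TestEvaluationSet:
    def test_fixed_seed_gives_byte_identical_msp_exports(self):
        a = synth.generate_evaluation_set(n_compounds=6, decoys_per_compound=2, n_fillers=3, seed=5)
        b = synth.generate_evaluation_set(n_compounds=6, decoys_per_compound=2, n_fillers=3, seed=5)
        assert [write_msp(x) for x in a] == [write_msp(y) for y in b]

    def test_pairing_and_library_composition(self):
        pred, exp, lib = synth.generate_evaluation_set(
            n_compounds=6, decoys_per_compound=2, n_fillers=3, seed=5
        )
        assert pred.ids() == exp.ids()
        assert len(lib) == 6 + 6 * 2 + 3

    def test_decoys_share_majority_of_fragment_mz(self):
        _, exp, lib = synth.generate_evaluation_set(
            n_compounds=4, decoys_per_compound=3, n_fillers=0, seed=9
        )
        for e in exp:
            frags = {p.mz for p in e.peaks if p.mz != float(e.nominal_mw)}
            for k in range(1, 4):
                decoy = lib[f"{e.id}_D{k}"]
                dfrags = {p.mz for p in decoy.peaks if p.mz != float(decoy.nominal_mw)}
                assert len(frags & dfrags) >= 0.5 * len(frags)


class TestTable2Fixture:
    def test_row_count(self):
        assert len(synth.table2_fixture()) == 38

    def test_known_rows_verbatim(self):
        rows = {c.mol_id: c for c in synth.table2_fixture()}
        assert (rows["5"].nominal_mw, rows["5"].exp_abundance, rows["5"].pred_abundance) == (126, 82.0, 32.0)
        assert rows["5"].signed_diff == -50.0
        assert (rows["65"].exp_abundance, rows["65"].pred_abundance) == (2.0, 100.0)
        assert rows["65"].signed_diff == 98.0
        assert rows["16"].signed_diff == 34.0

    def test_subclass_sizes(self):
        sizes = {}
        for c in synth.table2_fixture():
            sizes[c.subclass] = sizes.get(c.subclass, 0) + 1
        assert sizes == {
            "Pyrimidines": 8, "Xanthines": 5, "Hypoxanthines": 3, "Lumazines": 4,
            "Quinazolinediones": 3, "Remycins": 6, "Pyridopyrimidinediones": 5, "Others": 4,
        }


class TestParameterRecovery:
    def test_molion_bias_recovered_by_class_summary(self):
        spec = synth.ClassSpec("Recovery", molion_base_prob=0.0, molion_survival=(75.0, 85.0))
        bias = (-30.0, 5.0)
        comps = []
        master = np.random.SeedSequence(123)
        for i, child in enumerate(master.spawn(500)):
            g, p = child.spawn(2)
            exp = synth.generate_reference_spectrum(
                spec, synth._child_seed(g), mol_id=f"M{i}"
            )
            pred = synth.perturb_spectrum(
                exp,
                synth.PerturbationConfig(molion_shift=bias, seed=synth._child_seed(p)),
            )
            comps.append(mi.compare_molecular_ions(pred, exp))
        (cs,) = mi.class_summary(comps)
        # |N(-30, 5)| has mean ~30.03
        assert cs.mean_abs_diff == pytest.approx(30.0, abs=2.0)
        assert cs.n_under == 500
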