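"""Synthetic panel / e-nose generators: determinism and parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from odormix.fuzzy import FuzzyOdorModel
from odormix.perceptual import (
    MixtureObservation,
    build_interaction_matrix,
    mspe,
    predict_mixture,
)
from odormix.psychophysics import concentration_for_oi, fit_weber_fechner
from odormix.reference import reference_cos_matrix
from odormix.synthetic import (
    PanelModel,
    default_sensor_model,
    doubling_series,
    make_fixture_suite,
    simulate_binary_mixture_panel,
    simulate_enose_signals,
    simulate_enose_training,
    simulate_single_odorant_panel,
)


class TestSingleOdorantPanel:
    def test_noise_free_ratings_are_rounded_truth(self, toluene):
        ds = simulate_single_odorant_panel(
            toluene, panel=PanelModel(noise_sd=0.0), n_panelists=3, seed=0)
        for c, grp in ds.samples.groupby("concentration_ppm"):
            true_oi = ds.truth["true_oi"][c]
            assert (grp["oi"] == np.clip(round(true_oi), 0, 6)).all()

    def test_deterministic_under_seed(self, toluene):
        a = simulate_single_odorant_panel(toluene, seed=7).samples
        b = simulate_single_odorant_panel(toluene, seed=7).samples
        pd.testing.assert_frame_equal(a, b)
        c = simulate_single_odorant_panel(toluene, seed=8).samples
        assert not a["oi"].equals(c["oi"])

    def test_doubling_design_default(self, toluene):
        ds = simulate_single_odorant_panel(toluene, seed=0)
        concs = sorted(ds.samples["concentration_ppm"].unique())
        assert len(concs) == 5
        ratios = np.diff(np.log2(concs))
        assert np.allclose(ratios, 1.0)

    def test_law_recovery_within_three_se(self, profiles):
        for prof in profiles[:3]:
            ds = simulate_single_odorant_panel(
                prof, panel=PanelModel(noise_sd=0.2), n_panelists=10, seed=21)
            res = fit_weber_fechner(
                list(zip(ds.samples["concentration_ppm"], ds.samples["oi"])))
            assert abs(res.law.k_wf - prof.wf.k_wf) < 3 * res.std_errors["k_wf"]


class TestMixturePanel:
    def test_euclidean_truth_at_unit_level(self, profiles):
        cos = reference_cos_matrix("vectorial", 1)
        zero = type(cos).from_pairs(
            "vectorial", {pair: 0.0 for pair in [(a, b) for a, b in cos.pairs()]},
            oi_level=1)
        ds = simulate_binary_mixture_panel(profiles, zero, "vectorial", 1,
                                           PanelModel(noise_sd=0.0), seed=0)
        assert np.allclose(ds.samples["true_oi_ab"], math.sqrt(2))

    def test_noise_free_coefficient_recovery_is_exact(self, profiles):
        cos = reference_cos_matrix("vectorial", 2)
        ds = simulate_binary_mixture_panel(profiles, cos, "vectorial", 2,
                                           PanelModel(noise_sd=0.0), seed=0)
        # use the continuous truth (pre-rounding) -> exact inverse
        for row in ds.samples.drop_duplicates(["odorant_a", "odorant_b"]).itertuples():
            from odormix.perceptual import estimate_cos_vectorial
            est = estimate_cos_vectorial(
                MixtureObservation(2, 2, row.true_oi_ab))
            assert est.cos_ab == pytest.approx(cos.cos(row.odorant_a, row.odorant_b),
                                               abs=1e-9)

    def test_missing_pair_coefficient_is_error(self, profiles):
        cos = reference_cos_matrix("vectorial", 1)
        partial = type(cos)("vectorial", 1)
        with pytest.raises(KeyError):
            simulate_binary_mixture_panel(profiles[:3], partial, "vectorial", 1, seed=0)

    def test_monte_carlo_recovery_error_bounded(self, profiles):
        cos = reference_cos_matrix("vectorial", 2)
        ds = simulate_binary_mixture_panel(
            profiles, cos, "vectorial", 2,
            PanelModel(noise_sd=0.3, n_replicates=3), seed=0)
        obs = {
            (a, b): MixtureObservation(2.0, 2.0, float(grp["rating"].mean()), 3)
            for (a, b), grp in ds.samples.groupby(["odorant_a", "odorant_b"],
                                                  sort=False)}
        est = build_interaction_matrix(obs, "vectorial", oi_level=2)
        errors = [abs(est.cos(a, b) - cos.cos(a, b)) for a, b in est.pairs()]
        assert len(errors) == 28
        assert np.mean(errors) < 0.15


class TestSensorSignals:
    def test_zero_concentration_zero_noise_gives_baseline(self, profiles,
                                                          noiseless_sensor_model):
        sig = simulate_enose_signals({p.name: 0.0 for p in profiles},
                                     noiseless_sensor_model)
        for s, v in sig.items():
            assert v == pytest.approx(noiseless_sensor_model.baseline[s])

    def test_monotone_in_each_concentration(self, noiseless_sensor_model, toluene):
        lo = simulate_enose_signals({"toluene": 1.0}, noiseless_sensor_model)
        hi = simulate_enose_signals({"toluene": 2.0}, noiseless_sensor_model)
        assert all(hi[s] > lo[s] for s in lo)

    def test_mixture_suppression_subadditive(self, profiles, noiseless_sensor_model):
        a = simulate_enose_signals({"toluene": 2.0}, noiseless_sensor_model)
        b = simulate_enose_signals({"o-xylene": 2.0}, noiseless_sensor_model)
        ab = simulate_enose_signals({"toluene": 2.0, "o-xylene": 2.0},
                                    noiseless_sensor_model)
        for s in a:
            base = noiseless_sensor_model.baseline[s]
            assert ab[s] - base < (a[s] - base) + (b[s] - base)

    def test_deterministic_with_seed(self, profiles):
        sm = default_sensor_model(profiles, noise_sd=0.05)
        s1 = simulate_enose_signals({"toluene": 2.0}, sm, seed=3)
        s2 = simulate_enose_signals({"toluene": 2.0}, sm, seed=3)
        assert s1 == s2

    def test_mspe_decreases_as_sensor_noise_vanishes(self, profiles):
        """End-to-end: fuzzy predictions approach the generating mixture OI
        as measurement noise shrinks (fixed calibration, fixed seeds)."""
        cos = reference_cos_matrix("vectorial", 2)
        sm_train = default_sensor_model(profiles, noise_sd=0.05)
        training = simulate_enose_training(profiles, sm_train, n_per_level=5, seed=7)
        model = FuzzyOdorModel.train(training)
        errors = []
        for noise in (0.2, 0.05, 0.0):
            sm_test = default_sensor_model(profiles, noise_sd=noise)
            preds, truths = [], []
            test_seed = 1000
            for i, pa in enumerate(profiles):
                for pb in profiles[i + 1:]:
                    c = {pa.name: concentration_for_oi(pa.wf, 2),
                         pb.name: concentration_for_oi(pb.wf, 2)}
                    sig = simulate_enose_signals(c, sm_test, seed=test_seed)
                    test_seed += 1
                    preds.append(model.infer(sig))
                    truths.append(predict_mixture(
                        "vectorial", 2, 2, cos.cos(pa.name, pb.name)))
            errors.append(mspe(preds, truths))
        assert errors[0] >= errors[1] >= errors[2]


class TestFixtureSuite:
    def test_byte_identical_under_same_seed(self, tmp_path):
        m1 = make_fixture_suite(5, tmp_path / "a")
        m2 = make_fixture_suite(5, tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_checksums_verify(self, tmp_path):
        import hashlib
        import json

        outdir = tmp_path / "fx"
        make_fixture_suite(3, outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        for name, digest in manifest["files"].items():
            assert hashlib.sha256((outdir / name).read_bytes()).hexdigest() == digest

    def test_covers_all_odorants_and_pairs(self, tmp_path):
        outdir = tmp_path / "fx"
        manifest = make_fixture_suite(1, outdir)
        assert manifest["n_odorants"] == 8 and manifest["n_pairs"] == 28
        panel = pd.read_csv(outdir / "panel_single_odorant.csv")
        assert panel["odorant"].nunique() == 8
        mix = pd.read_csv(outdir / "panel_mixtures_level1.csv")
        assert mix.groupby(["odorant_a", "odorant_b"]).ngroups == 28
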