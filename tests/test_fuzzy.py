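"""Membership calibration, rule learning and Mamdani inference."""

import math

import numpy as np
import pytest

from odormix.fuzzy import (
    CalibrationError,
    FuzzyOdorModel,
    FuzzyRule,
    GaussianMF,
    LabeledSample,
    NoRuleFiredError,
    OutputConfig,
    RuleBase,
    SensorMembershipSet,
    calibrate_membership,
    default_output_mfs,
    fuzzify,
    infer,
    learn_rules,
    validate,
)
from odormix.psychophysics import concentration_for_oi
from odormix.synthetic import simulate_enose_signals, simulate_enose_training

SENSORS = ("S1", "S2", "S3")


def make_mfs(means_by_level, sd=0.5, sensors=SENSORS):
    """Membership set with identical level means on every sensor."""
    return SensorMembershipSet({
        s: {lv: GaussianMF(m, sd) for lv, m in means_by_level.items()}
        for s in sensors})


def samples_at_levels(means_by_level, n=2, jitter=0.0, sensors=SENSORS, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for lv, m in means_by_level.items():
        for _ in range(n):
            out.append(LabeledSample(
                {s: m + (rng.normal(0, jitter) if jitter else 0.0) for s in sensors},
                oi_label=lv))
    return out


WELL_SEPARATED = {1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0, 5: 5.0}


def centroid_oracle(signals, rulebase, mfs, output_mfs, step):
    """Brute-force min/min/max/centroid on an explicit fine grid."""
    grid = np.arange(0.0, 6.0 + step / 2, step)
    agg = np.zeros_like(grid)
    for rule in rulebase.rules:
        h = min(
            math.exp(-(signals[s] - mfs.mf(s, lv).mean) ** 2
                     / (2 * mfs.mf(s, lv).sd ** 2))
            for s, lv in rule.antecedent.items())
        out = output_mfs[rule.consequent]
        clipped = np.minimum(h, np.exp(-(grid - out.mean) ** 2 / (2 * out.sd ** 2)))
        agg = np.maximum(agg, clipped)
    return float((grid * agg).sum() / agg.sum())


class TestCalibration:
    def test_hand_statistics(self):
        training = [LabeledSample({"S1": v, "S2": v + 1}, 1) for v in (1.0, 2.0, 3.0)]
        training += [LabeledSample({"S1": v, "S2": v + 1}, 2) for v in (5.0, 6.0, 7.0)]
        mfs = calibrate_membership(training)
        assert mfs.mf("S1", 1).mean == pytest.approx(2.0)
        assert mfs.mf("S1", 1).sd == pytest.approx(1.0)
        assert mfs.mf("S2", 2).mean == pytest.approx(7.0)

    def test_recovers_generating_gaussians(self):
        rng = np.random.default_rng(11)
        n, true_sd = 50, 0.3
        training = []
        for lv, mean in WELL_SEPARATED.items():
            for _ in range(n):
                training.append(LabeledSample(
                    {s: rng.normal(mean, true_sd) for s in SENSORS}, lv))
        mfs = calibrate_membership(training)
        for lv, mean in WELL_SEPARATED.items():
            for s in SENSORS:
                assert abs(mfs.mf(s, lv).mean - mean) < 3 * true_sd / math.sqrt(n)

    def test_missing_cell_names_sensor_and_level(self):
        training = samples_at_levels({1: 1.0, 2: 2.0})
        training.append(LabeledSample({s: 3.0 for s in SENSORS}, 3))  # one sample only
        with pytest.raises(CalibrationError, match=r"level 3"):
            calibrate_membership(training)

    def test_zero_variance_falls_back_to_sd_floor(self):
        mfs = calibrate_membership(samples_at_levels({1: 1.0, 2: 3.0}, n=3))
        assert mfs.mf("S1", 1).sd == pytest.approx(0.01 * 2.0)  # 1% of range

    def test_non_contiguous_levels_rejected(self):
        with pytest.raises(CalibrationError, match="contiguous"):
            calibrate_membership(samples_at_levels({1: 1.0, 3: 3.0}))


class TestFuzzification:
    def test_peak_membership_is_one(self):
        mf = GaussianMF(2.0, 0.5)
        assert mf.membership(2.0) == 1.0

    def test_one_sd_away(self):
        mf = GaussianMF(2.0, 0.5)
        assert mf.membership(2.5) == pytest.approx(math.exp(-0.5))

    def test_degrees_match_direct_formula(self):
        mfs = {lv: GaussianMF(float(lv), 0.4) for lv in range(1, 6)}
        x = 2.7
        degrees = fuzzify(x, mfs)
        for lv, mf in mfs.items():
            assert degrees[lv] == pytest.approx(
                math.exp(-((x - lv) ** 2) / (2 * 0.4**2)))

    def test_unknown_sensor_rejected(self):
        mfs = make_mfs(WELL_SEPARATED)
        with pytest.raises(KeyError):
            mfs.fuzzify("S99", 1.0)


class TestRuleLearning:
    def test_samples_at_means_give_homogeneous_rules(self):
        training = samples_at_levels(WELL_SEPARATED, n=2)
        mfs = make_mfs(WELL_SEPARATED)
        rb = learn_rules(training, mfs)
        assert len(rb) == 5
        for rule in rb.rules:
            assert set(rule.antecedent.values()) == {rule.consequent}
            assert rule.degree == pytest.approx(1.0)

    def test_conflicting_samples_resolved_by_degree(self):
        mfs = make_mfs({1: 1.0, 2: 2.0})
        # both samples map to the all-level-1 antecedent but disagree on label
        training = [LabeledSample({s: 1.0 for s in SENSORS}, 2),   # degree 1.0
                    LabeledSample({s: 1.2 for s in SENSORS}, 1)]   # degree < 1
        rb = learn_rules(training, mfs, include_homogeneous=False)
        assert len(rb) == 1
        assert rb.rules[0].consequent == 2

    def test_homogeneous_rules_take_precedence(self):
        mfs = make_mfs({1: 1.0, 2: 2.0})
        training = [LabeledSample({s: 1.0 for s in SENSORS}, 2)]
        rb = learn_rules(training, mfs, include_homogeneous=True)
        all_ones = {s: 1 for s in SENSORS}
        winner = next(r for r in rb.rules if dict(r.antecedent) == all_ones)
        assert winner.consequent == 1

    def test_rule_count_bounded_by_distinct_antecedents(self):
        rng = np.random.default_rng(4)
        mfs = make_mfs(WELL_SEPARATED)
        training = [LabeledSample({s: rng.uniform(0.5, 5.5) for s in SENSORS},
                                  int(rng.integers(1, 6))) for _ in range(60)]
        rb = learn_rules(training, mfs, include_homogeneous=False)
        antecedents = set()
        for samp in training:
            ant = []
            for s in SENSORS:
                degrees = mfs.fuzzify(s, samp.signals[s])
                ant.append(max(sorted(degrees), key=lambda lv: degrees[lv]))
            antecedents.add(tuple(ant))
        assert len(rb) <= len(antecedents)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            learn_rules([], make_mfs(WELL_SEPARATED))


class TestInference:
    def setup_method(self):
        self.mfs = make_mfs(WELL_SEPARATED, sd=0.2)
        self.rb = RuleBase([FuzzyRule({s: lv for s in SENSORS}, lv)
                            for lv in WELL_SEPARATED])

    def test_signals_at_level_means_return_level(self):
        for lv, mean in WELL_SEPARATED.items():
            oi = infer({s: mean for s in SENSORS}, self.rb, self.mfs)
            assert oi == pytest.approx(lv, abs=0.02)

    def test_equal_firing_of_adjacent_levels_gives_midpoint(self):
        # halfway between the level-2 and level-3 means fires both equally
        oi = infer({s: 2.5 for s in SENSORS}, self.rb, self.mfs)
        assert oi == pytest.approx(2.5, abs=0.02)

    def test_centroid_matches_fine_grid_oracle(self):
        rng = np.random.default_rng(9)
        out_mfs = default_output_mfs(sd=0.4)
        for _ in range(5):
            # coherent signal vectors (all sensors near a common level):
            # incoherent ones legitimately fire no rule
            center = rng.uniform(1.0, 5.0)
            signals = {s: float(center + rng.uniform(-0.3, 0.3)) for s in SENSORS}
            got = infer(signals, self.rb, self.mfs, output_mfs=out_mfs,
                        config=OutputConfig(grid_step=0.01))
            want = centroid_oracle(signals, self.rb, self.mfs, out_mfs, step=0.001)
            assert got == pytest.approx(want, abs=1e-3)

    def test_invariant_under_sensor_relabeling(self):
        oi1 = infer({"S1": 2.0, "S2": 2.1, "S3": 1.9}, self.rb, self.mfs)
        # permute the roles of the sensors: identical MFs => same answer
        oi2 = infer({"S1": 1.9, "S2": 2.0, "S3": 2.1}, self.rb, self.mfs)
        assert oi1 == pytest.approx(oi2, abs=1e-12)

    def test_output_continuous_in_each_signal(self):
        # finite-difference scan: steps of 0.01 in one signal never jump
        # more than ~ the local Lipschitz scale set by the MF widths
        base = {s: 2.3 for s in SENSORS}
        prev = infer(base, self.rb, self.mfs)
        for x in np.arange(2.3, 3.3, 0.01):
            cur = infer({**base, "S1": float(x)}, self.rb, self.mfs)
            assert abs(cur - prev) < 0.1
            prev = cur

    def test_centroid_within_hull_of_fired_centers(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            center = rng.uniform(1.0, 5.0)
            signals = {s: float(center + rng.uniform(-0.25, 0.25)) for s in SENSORS}
            oi = infer(signals, self.rb, self.mfs)
            fired = [r.consequent for r in self.rb.rules
                     if min(self.mfs.mf(s, r.antecedent[s]).membership(signals[s])
                            for s in SENSORS) >= 1e-6]
            # 0.01 pad: truncation of the outermost Gaussians at the scale ends
            assert min(fired) - 0.01 <= oi <= max(fired) + 0.01

    def test_no_rule_fired_diagnostics(self):
        mfs = make_mfs(WELL_SEPARATED, sd=0.05)
        with pytest.raises(NoRuleFiredError) as exc:
            infer({s: 40.0 for s in SENSORS}, self.rb, mfs)
        assert exc.value.strengths

    def test_signal_sensor_mismatch(self):
        with pytest.raises(KeyError):
            infer({"S1": 1.0}, self.rb, self.mfs)


class TestValidation:
    def test_perfect_predictions(self):
        report = validate([1, 2, 3], [1, 2, 3])
        assert report.mspe == 0.0
        assert (report.table["residual"] == 0).all()

    def test_constant_offset(self):
        assert validate([2, 3, 4], [1, 2, 3]).mspe == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            validate([1], [1, 2])


class TestEndToEnd:
    def test_closure_on_noiseless_synthetic_signals(self, toluene,
                                                    noiseless_sensor_model,
                                                    toluene_fuzzy_model):
        for level in range(1, 6):
            c = concentration_for_oi(toluene.wf, level)
            sig = simulate_enose_signals({"toluene": c}, noiseless_sensor_model)
            assert toluene_fuzzy_model.infer(sig) == pytest.approx(level, abs=0.1)

    def test_model_json_roundtrip(self, toluene_fuzzy_model, toluene,
                                  noiseless_sensor_model):
        restored = FuzzyOdorModel.from_json(toluene_fuzzy_model.to_json())
        sig = simulate_enose_signals(
            {"toluene": concentration_for_oi(toluene.wf, 3)}, noiseless_sensor_model)
        assert restored.infer(sig) == pytest.approx(toluene_fuzzy_model.infer(sig),
                                                    abs=1e-12)

    def test_validation_report_deterministic_under_seed(self, profiles):
        from odormix.synthetic import default_sensor_model

        sm = default_sensor_model(profiles, noise_sd=0.05)
        training = simulate_enose_training(profiles[:2], sm, seed=13)
        model = FuzzyOdorModel.train(training)
        preds = []
        for _ in range(2):
            sm2 = default_sensor_model(profiles, noise_sd=0.05)
            sig = simulate_enose_signals(
                {"toluene": concentration_for_oi(profiles[2].wf, 2)}, sm2, seed=77)
            preds.append(model.infer(sig))
        assert preds[0] == preds[1]
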