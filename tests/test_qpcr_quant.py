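import numpy as np
import pandas as pd
import pytest

from somamark import qpcr_quant as qq
from somamark import synthetic_data as sd


def make_plate(cq_by_sample, target="mito", reference="nuclear_ref",
               groups=None, metrics=None):
    """Tiny plate: one well per (sample, target), reference Cq fixed."""
    rows = []
    for i, (sample, cq) in enumerate(cq_by_sample.items()):
        group = (groups or {}).get(sample, "g0")
        rows.append({"well": f"A{i}", "sample": sample, "target": target,
                     "cq": cq, "replicate_group": f"{sample}:t",
                     "group": group})
        rows.append({"well": f"B{i}", "sample": sample, "target": reference,
                     "cq": 20.0, "replicate_group": f"{sample}:r",
                     "group": group})
    wells = pd.DataFrame(rows)
    default_metrics = {"efficiency_pct": {target: 95.0, reference: 98.0},
                       "standard_curve_r2": 0.995, "ntc_cq": 40.0}
    return qq.QpcrPlate(wells, metrics if metrics is not None
                        else default_metrics)


class TestQcRun:
    def test_clean_run_passes(self):
        plate = make_plate({"a": 24.0, "b": 24.1})
        report = qq.qc_run(plate)
        assert report.passed
        assert report.failed_rules == ()

    def test_replicate_sd_rule(self):
        wells = pd.DataFrame({
            "well": ["A1", "A2"], "sample": ["a", "a"],
            "target": ["mito", "mito"], "cq": [24.0, 24.5],
            "replicate_group": ["a:mito", "a:mito"], "group": ["g", "g"]})
        plate = qq.QpcrPlate(wells, {"efficiency_pct": 100.0,
                                     "standard_curve_r2": 0.99,
                                     "ntc_cq": 40.0})
        report = qq.qc_run(plate)  # SD of {24.0, 24.5} = 0.354 > 0.20
        assert not report.passed
        assert "replicate_sd" in report.failed_rules

    def test_efficiency_window(self):
        plate = make_plate({"a": 24.0},
                           metrics={"efficiency_pct": 85.0,
                                    "standard_curve_r2": 0.99,
                                    "ntc_cq": 40.0})
        assert "efficiency" in qq.qc_run(plate).failed_rules

    def test_early_ntc_is_contamination(self):
        plate = make_plate({"a": 24.0},
                           metrics={"efficiency_pct": 100.0,
                                    "standard_curve_r2": 0.99,
                                    "ntc_cq": 35.0})
        assert "ntc" in qq.qc_run(plate).failed_rules

    def test_high_sample_cq_fails(self):
        plate = make_plate({"a": 31.0})
        assert "sample_cq" in qq.qc_run(plate).failed_rules

    def test_poor_standard_curve_fails(self):
        plate = make_plate({"a": 24.0},
                           metrics={"efficiency_pct": 100.0,
                                    "standard_curve_r2": 0.97,
                                    "ntc_cq": 40.0})
        assert "standard_curve_r2" in qq.qc_run(plate).failed_rules

    def test_missing_metric_flagged_not_evaluable(self):
        plate = make_plate({"a": 24.0}, metrics={})
        report = qq.qc_run(plate)
        assert not report.passed
        assert "efficiency_not_evaluable" in report.failed_rules

    def test_matches_independent_rule_reevaluation(self, rng):
        """Oracle: re-evaluate every rule predicate directly on 20
        randomised plates and compare failure sets."""
        for trial in range(20):
            cq = {f"s{i}": float(rng.uniform(20, 33)) for i in range(4)}
            metrics = {"efficiency_pct": float(rng.uniform(80, 115)),
                       "standard_curve_r2": float(rng.uniform(0.95, 1.0)),
                       "ntc_cq": float(rng.uniform(33, 42))}
            plate = make_plate(cq, metrics=metrics)
            expected = set()
            if metrics["ntc_cq"] < 38:
                expected.add("ntc")
            if any(v > 30 for v in cq.values()):
                expected.add("sample_cq")
            if not 90 <= metrics["efficiency_pct"] <= 110:
                expected.add("efficiency")
            if metrics["standard_curve_r2"] < 0.980:
                expected.add("standard_curve_r2")
            report = qq.qc_run(plate)
            assert set(report.failed_rules) == expected
            assert report.passed == (not expected)


class TestRelativeQuantity:
    def test_identical_cq_everywhere_gives_unit_ratios(self):
        plate = make_plate({"a": 24.0, "b": 24.0},
                           groups={"a": "w0", "b": "w4"})
        out = qq.relative_quantity(plate.wells, baseline_group="w0")
        assert np.allclose(out["ratio"], 1.0)

    def test_one_cycle_earlier_doubles_at_perfect_efficiency(self):
        plate = make_plate({"a": 24.0, "b": 23.0},
                           groups={"a": "w0", "b": "w4"})
        out = qq.relative_quantity(plate.wells, baseline_group="w0")
        assert out.loc[out["sample"] == "b", "ratio"].iloc[0] == \
            pytest.approx(2.0)

    def test_efficiency_correction(self):
        plate = make_plate({"a": 24.0, "b": 23.0},
                           groups={"a": "w0", "b": "w4"})
        out = qq.relative_quantity(plate.wells, baseline_group="w0",
                                   efficiency_target=0.9)
        assert out.loc[out["sample"] == "b", "ratio"].iloc[0] == \
            pytest.approx(1.9)

    def test_equals_two_to_minus_ddcq_exactly(self, rng):
        """At E=1 the efficiency-corrected form collapses to the
        textbook 2^(-ddCq)."""
        samples = {f"s{i}": float(rng.uniform(20, 26)) for i in range(6)}
        groups = {s: ("w0" if i < 3 else "w4")
                  for i, s in enumerate(samples)}
        plate = make_plate(samples, groups=groups)
        out = qq.relative_quantity(plate.wells, baseline_group="w0")
        base_mean = np.mean([samples[s] for s in samples
                             if groups[s] == "w0"])
        for _, row in out.iterrows():
            ddcq = (samples[row["sample"]] - base_mean) - 0.0
            assert row["ratio"] == pytest.approx(2.0 ** (-ddcq))

    def test_missing_reference_excluded_with_warning(self):
        plate = make_plate({"a": 24.0, "b": 24.0},
                           groups={"a": "w0", "b": "w0"})
        wells = plate.wells[~((plate.wells["sample"] == "b")
                              & (plate.wells["target"] == "nuclear_ref"))]
        with pytest.warns(UserWarning, match="lacking the reference"):
            out = qq.relative_quantity(wells, baseline_group="w0")
        assert list(out["sample"]) == ["a"]


class TestTsRatio:
    def test_one_cycle_later_halves(self):
        plate = make_plate({"a": 24.0, "b": 25.0}, target="telomere",
                           reference="single_copy_gene",
                           groups={"a": "w0", "b": "w4"})
        out = qq.ts_ratio(plate.wells, baseline_group="w0")
        assert out.loc[out["sample"] == "b", "ratio"].iloc[0] == \
            pytest.approx(0.5)

    def test_halved_template_recovered_from_simulated_plate(self):
        truth = pd.DataFrame({
            "sample": [f"m{i}" for i in range(16)],
            "group": ["w0"] * 8 + ["w4"] * 8,
            "ratio": [1.0] * 8 + [0.5] * 8})
        wells = sd.simulate_qpcr_plate(truth, target="telomere",
                                       reference="single_copy_gene",
                                       cq_noise_sd=0.05, seed=5)
        out = qq.ts_ratio(wells, baseline_group="w0")
        mean_w4 = out.loc[out["group"] == "w4", "ratio"].mean()
        assert mean_w4 == pytest.approx(0.5, rel=0.1)


class TestFoldChange:
    def test_trivial_values(self):
        out = qq.fold_change([2.0, 2.0, 5.0], ["w0", "w0", "w4"], "w0")
        np.testing.assert_allclose(out, [1.0, 1.0, 2.5])

    def test_baseline_mean_exactly_one(self, rng):
        values = rng.lognormal(0, 0.4, 60)
        groups = np.repeat(["w0", "w2", "w4"], 20)
        out = qq.fold_change(values, groups, "w0")
        assert out[groups == "w0"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_empty_or_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            qq.fold_change([1.0], ["w4"], "w0")
        with pytest.raises(ValueError, match="positive"):
            qq.fold_change([0.0, 1.0], ["w0", "w4"], "w0")

    def test_programmed_stress_series_fold_recovered(self):
        """Plate-simulator truth: a 2.4-fold mtDNA rise at week 4 is
        recovered by ddCq + fold-change within replicate noise."""
        truth = pd.DataFrame({
            "sample": [f"m{i}" for i in range(24)],
            "group": np.repeat(["w0", "w2", "w4"], 8),
            "ratio": np.repeat([1.0, 1.5, 2.4], 8)})
        wells = sd.simulate_qpcr_plate(truth, cq_noise_sd=0.05, seed=8)
        ratios = qq.relative_quantity(wells, baseline_group="w0")
        folds = qq.fold_change(ratios["ratio"], ratios["group"], "w0")
        w4 = folds[(ratios["group"] == "w4").to_numpy()]
        assert w4.mean() == pytest.approx(2.4, rel=0.05)
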