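"""Dose-response quantification: double normalization, paired tests, IC estimation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mirchemo import chemo
from mirchemo.chemo import DoseResponseAnalysis


def plate_frame(rows):
    return pd.DataFrame(rows, columns=["condition", "dose_nM", "bio_rep", "tech_rep", "signal"])


def simple_plate(condition, by_rep):
    """{bio_rep: {dose: signal}} -> single-tech-rep plate rows."""
    rows = []
    for rep, doses in by_rep.items():
        for dose, sig in doses.items():
            rows.append((condition, dose, rep, "t1", sig))
    return plate_frame(rows)


class TestRelativeSurvival:
    def test_fraction_of_vehicle(self):
        plate = simple_plate("c", {"b1": {0: 1.0, 100: 0.4}})
        curve = chemo.relative_survival_vs_vehicle(plate, "c")
        assert curve.set_index("dose_nM").loc[100, "mean_relative_survival"] == pytest.approx(0.4)
        assert curve.set_index("dose_nM").loc[0, "mean_relative_survival"] == pytest.approx(1.0)

    def test_replicate_mean_and_sd(self):
        plate = simple_plate(
            "c",
            {"b1": {0: 1.0, 100: 0.35}, "b2": {0: 1.0, 100: 0.40}, "b3": {0: 1.0, 100: 0.45}},
        )
        row = chemo.relative_survival_vs_vehicle(plate, "c").set_index("dose_nM").loc[100]
        assert row["mean_relative_survival"] == pytest.approx(0.40)
        assert row["sd"] == pytest.approx(0.05)

    def test_missing_vehicle_rejected(self):
        plate = simple_plate("c", {"b1": {100: 0.4}})
        with pytest.raises(ValueError, match="vehicle"):
            chemo.relative_survival_vs_vehicle(plate, "c")

    def test_rescaling_invariance_per_bio_rep(self):
        """Relative quantities are invariant to linear rescaling of raw signals."""
        base = {"b1": {0: 1.0, 100: 0.5}, "b2": {0: 0.9, 100: 0.36}}
        scaled = {r: {d: 7.3 * s for d, s in doses.items()} for r, doses in base.items()}
        c1 = chemo.relative_survival_vs_vehicle(simple_plate("c", base), "c")
        c2 = chemo.relative_survival_vs_vehicle(simple_plate("c", scaled), "c")
        pd.testing.assert_frame_equal(c1, c2)


class TestDoubleNormalization:
    def test_ratio_to_control(self):
        target = chemo.relative_survival_vs_vehicle(
            simple_plate("t", {"b1": {0: 1.0, 100: 0.5}}), "t"
        )
        control = chemo.relative_survival_vs_vehicle(
            simple_plate("c", {"b1": {0: 1.0, 100: 0.4}}), "c"
        )
        out = chemo.relative_to_control_transfection(target, control)
        assert out.set_index("dose_nM").loc[100, "mean_ratio"] == pytest.approx(1.25)

    def test_equal_curves_ratio_one(self):
        a = chemo.relative_survival_vs_vehicle(
            simple_plate("t", {"b1": {0: 1.0, 50: 0.7, 100: 0.4}}), "t"
        )
        out = chemo.relative_to_control_transfection(a, a)
        np.testing.assert_allclose(out["mean_ratio"], 1.0)

    def test_dose_grid_mismatch_rejected(self):
        a = chemo.relative_survival_vs_vehicle(simple_plate("t", {"b1": {0: 1, 50: 0.5}}), "t")
        b = chemo.relative_survival_vs_vehicle(simple_plate("c", {"b1": {0: 1, 60: 0.5}}), "c")
        with pytest.raises(ValueError, match="dose"):
            chemo.relative_to_control_transfection(a, b)


class TestPairedT:
    def test_textbook_example(self):
        res = chemo.paired_one_tailed_t([0.60, 0.55, 0.62], [0.50, 0.48, 0.51], "greater")
        assert res.statistic == pytest.approx(7.765, abs=0.01)
        assert res.p_value < 0.01 and res.df == 2

    def test_identical_vectors_half(self):
        res = chemo.paired_one_tailed_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "greater")
        assert res.p_value == 0.5 and res.degenerate

    def test_direction_swap_complements_p(self):
        x, y = [0.6, 0.5, 0.7, 0.55], [0.5, 0.52, 0.6, 0.5]
        pg = chemo.paired_one_tailed_t(x, y, "greater").p_value
        pl = chemo.paired_one_tailed_t(x, y, "less").p_value
        assert pg + pl == pytest.approx(1.0)

    def test_constant_nonzero_difference_degenerate(self):
        res = chemo.paired_one_tailed_t([2.0, 3.0], [1.0, 2.0], "greater")
        assert res.degenerate and res.p_value == 0.0

    def test_matches_exact_sign_flip_permutation(self):
        """One-tailed t p-value tracks the exact paired permutation p on n=6."""
        x = np.array([0.62, 0.55, 0.60, 0.58, 0.64, 0.57])
        y = np.array([0.50, 0.52, 0.55, 0.51, 0.60, 0.56])
        d = x - y
        perm_means = [np.mean(d * np.array(s)) for s in itertools.product([1, -1], repeat=6)]
        p_perm = np.mean([m >= np.mean(d) - 1e-12 for m in perm_means])
        res = chemo.paired_one_tailed_t(x, y, "greater")
        assert res.p_value == pytest.approx(p_perm, abs=0.02)


class TestClonogenic:
    def test_surviving_fraction(self):
        assert chemo.surviving_fraction(30, 100, 60, 100) == pytest.approx(0.5)
        assert chemo.surviving_fraction(60, 100, 60, 100) == pytest.approx(1.0)

    def test_seeding_scale_invariance(self):
        assert chemo.surviving_fraction(30, 100, 60, 100) == pytest.approx(
            chemo.surviving_fraction(60, 200, 120, 200)
        )

    def test_zero_vehicle_pe_rejected(self):
        with pytest.raises(ValueError):
            chemo.surviving_fraction(5, 100, 0, 100)


class TestEstimateIc:
    def test_log_midpoint(self):
        assert chemo.estimate_ic([1.0, 100.0], [1.0, 0.0], 0.5) == pytest.approx(10.0)

    def test_exact_grid_hit(self):
        assert chemo.estimate_ic([10, 30, 100], [0.8, 0.5, 0.1], 0.5) == pytest.approx(30.0)

    def test_unbracketed_level_rejected(self):
        with pytest.raises(ValueError, match="not bracketed"):
            chemo.estimate_ic([10, 100], [0.9, 0.6], 0.25)

    def test_logistic_recovery_within_ten_percent(self):
        doses = np.array([5, 15, 50, 150, 500, 1500], dtype=float)
        surv = 1 / (1 + doses / 50.0)
        assert chemo.estimate_ic(doses, surv, 0.5) == pytest.approx(50.0, rel=0.10)

    def test_monotone_under_uniform_resistance_shift(self):
        doses = np.array([5, 15, 50, 150, 500, 1500], dtype=float)
        sens = 1 / (1 + doses / 50.0)
        resist = 1 / (1 + doses / 120.0)
        assert chemo.estimate_ic(doses, resist, 0.5) > chemo.estimate_ic(doses, sens, 0.5)


class TestResistanceRatio:
    def test_resistant_vs_parental(self):
        assert chemo.resistance_ratio(25.0, 2.0) == pytest.approx(12.5)
        assert chemo.resistance_ratio(2.0, 2.0) == pytest.approx(1.0)

    def test_inverts_under_swap(self):
        assert chemo.resistance_ratio(25, 2) == pytest.approx(1 / chemo.resistance_ratio(2, 25))


class TestDoseResponseAnalysis:
    def test_fit_and_compare_on_synthetic_plate(self):
        from mirchemo.simulate import SimulationConfig, gen_viability

        cfg = SimulationConfig(seed=31)
        dra = DoseResponseAnalysis().fit(gen_viability(cfg))
        assert set(dra.conditions_) == {"mimic", "mimic-control"}
        table = dra.compare("mimic", "mimic-control", "greater")
        # true IC50 is doubled, so mid-dose survival ratios exceed 1
        mid = table[table["dose_nM"].isin([125.0, 250.0])]
        assert (mid["mean_ratio"] > 1).all()
        assert (mid["p_value"] < 0.05).all()

    def test_ic_ratio_recovery(self):
        from mirchemo.simulate import SimulationConfig, gen_viability

        ratios = []
        for seed in range(40, 50):
            dra = DoseResponseAnalysis().fit(gen_viability(SimulationConfig(seed=seed)))
            ratios.append(dra.ic("mimic") / dra.ic("mimic-control"))
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)
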