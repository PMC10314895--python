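import numpy as np
import pandas as pd
import pytest

from degradomap import assayfit, simgen
from degradomap.assayfit import BellFit, FourPLFit

CONC8 = np.logspace(-9, -4, 8)
TRUTH_4PL = FourPLFit(top=100.0, bottom=0.0, ic50=1e-6, hill=1.0)
TRUTH_BELL = BellFit(baseline=5.0, amplitude=90.0, ec50_rise=3e-8, hill_rise=1.2,
                     ec50_fall=3e-6, hill_fall=1.5)


class TestNormalizeReporter:
    @pytest.mark.parametrize("raw,expected", [(900.0, 100.0), (100.0, 0.0), (500.0, 50.0)])
    def test_percent_activity(self, raw, expected):
        assert assayfit.normalize_reporter(raw, 100.0, 900.0) == expected

    def test_degenerate_controls_error(self):
        with pytest.raises(ValueError):
            assayfit.normalize_reporter(1.0, 5.0, 5.0)


class TestFit4PL:
    def test_noiseless_recovery(self):
        data = simgen.simulate_dose_response(TRUTH_4PL, CONC8)
        fit = assayfit.fit_4pl(data)
        assert fit.status == "ok"
        assert fit.pic50 == pytest.approx(6.0, abs=1e-3)
        assert fit.hill == pytest.approx(1.0, abs=1e-3)

    def test_midpoint_identity(self):
        data = simgen.simulate_dose_response(TRUTH_4PL, CONC8)
        fit = assayfit.fit_4pl(data)
        assert fit.predict(fit.ic50) == pytest.approx((fit.top + fit.bottom) / 2)

    def test_scale_equivariance(self):
        data = simgen.simulate_dose_response(TRUTH_4PL, CONC8)
        scaled = data.copy()
        scaled["concentration_M"] *= 100.0
        fit = assayfit.fit_4pl(data)
        fit_scaled = assayfit.fit_4pl(scaled)
        assert fit_scaled.ic50 == pytest.approx(100.0 * fit.ic50, rel=1e-3)

    def test_rising_curve_canonicalized(self):
        rising = FourPLFit(top=100.0, bottom=0.0, ic50=1e-6, hill=-1.0)
        fit = assayfit.fit_4pl(simgen.simulate_dose_response(rising, CONC8))
        assert fit.top >= fit.bottom
        assert fit.pic50 == pytest.approx(6.0, abs=1e-3)

    def test_flat_data_unidentifiable(self):
        flat = FourPLFit(top=50.0, bottom=50.0, ic50=1e-6, hill=1.0)
        fit = assayfit.fit_4pl(simgen.simulate_dose_response(flat, CONC8))
        assert fit.status == "unidentifiable"
        assert np.isnan(fit.ic50)

    def test_too_few_concentrations(self):
        data = simgen.simulate_dose_response(TRUTH_4PL, CONC8[:4])
        with pytest.raises(ValueError, match="distinct concentrations"):
            assayfit.fit_4pl(data)

    def test_noisy_recovery_median_error(self):
        errors = []
        for seed in range(10):
            data = simgen.simulate_dose_response(TRUTH_4PL, CONC8, noise_sd=5.0,
                                                 n_replicates=3, seed=seed)
            errors.append(abs(assayfit.fit_4pl(data).pic50 - 6.0))
        assert np.median(errors) <= 0.1


class TestFitBell:
    def test_noiseless_peak_recovery(self):
        conc = np.logspace(-9.5, -4, 12)
        fit = assayfit.fit_bell(simgen.simulate_dose_response(TRUTH_BELL, conc))
        assert fit.status == "ok"
        assert fit.ec50_rise < fit.ec50_fall
        grid = np.logspace(-9.5, -4, 20001)
        true_peak = grid[np.argmax(TRUTH_BELL.predict(grid))]
        assert fit.peak_conc == pytest.approx(true_peak, rel=0.10)

    def test_rise_then_fall_with_unique_interior_maximum(self):
        grid = np.logspace(-9.5, -4, 2001)
        curve = TRUTH_BELL.predict(grid)
        peak = int(np.argmax(curve))
        assert 0 < peak < len(grid) - 1
        assert np.all(np.diff(curve[:peak + 1]) >= -1e-9)
        assert np.all(np.diff(curve[peak:]) <= 1e-9)

    def test_monotone_data_flagged_degenerate(self):
        fit = assayfit.fit_bell(simgen.simulate_dose_response(TRUTH_4PL, CONC8))
        assert fit.status == "degenerate"

    def test_zero_amplitude_flagged_flat(self):
        flat = BellFit(baseline=30.0, amplitude=0.0, ec50_rise=1e-7, hill_rise=1,
                       ec50_fall=1e-5, hill_fall=1)
        fit = assayfit.fit_bell(simgen.simulate_dose_response(flat, CONC8))
        assert fit.status == "flat"


class TestSelectModel:
    def test_selects_generative_model(self):
        conc = np.logspace(-9.5, -4, 10)
        bell_data = simgen.simulate_dose_response(TRUTH_BELL, conc, noise_sd=4.0,
                                                  n_replicates=2, seed=1)
        four_data = simgen.simulate_dose_response(TRUTH_4PL, conc, noise_sd=4.0,
                                                  n_replicates=2, seed=2)
        assert assayfit.select_model(bell_data)["selected"] == "bell"
        assert assayfit.select_model(four_data)["selected"] == "four_pl"

    def test_small_sample_correction_requires_enough_points(self):
        data = simgen.simulate_dose_response(TRUTH_4PL, CONC8)   # n=8, bell k+1=8
        with pytest.raises(ValueError, match="n > k"):
            assayfit.select_model(data)


class TestQPCR:
    def _records(self, conditions, ct_t, ct_h):
        return pd.DataFrame({"condition": conditions, "ct_target": ct_t,
                             "ct_housekeeping": ct_h})

    def test_equal_cts_give_fold_one(self):
        rec = self._records(["dmso", "drug"], [20.0, 20.0], [15.0, 15.0])
        out = assayfit.qpcr_relative_expression(rec, "dmso")
        assert out["drug"] == pytest.approx(1.0)

    def test_one_cycle_drop_doubles_expression(self):
        rec = self._records(["dmso", "drug"], [20.0, 19.0], [15.0, 15.0])
        out = assayfit.qpcr_relative_expression(rec, "dmso")
        assert out["drug"] == pytest.approx(2.0)

    def test_matches_hand_computed_oracle(self, rng):
        conditions = ["dmso", "a", "b", "c"]
        rec = self._records(np.repeat(conditions, 2),
                            rng.uniform(18, 25, 8), rng.uniform(14, 16, 8))
        out = assayfit.qpcr_relative_expression(rec, "dmso")
        grouped = rec.groupby("condition").mean()
        dct = grouped["ct_target"] - grouped["ct_housekeeping"]
        for cond in conditions:
            assert out[cond] == pytest.approx(2.0 ** -(dct[cond] - dct["dmso"]))

    def test_missing_housekeeping_errors(self):
        rec = self._records(["dmso", "drug"], [20.0, 19.0], [15.0, np.nan])
        with pytest.raises(ValueError, match="missing Ct"):
            assayfit.qpcr_relative_expression(rec, "dmso")


class TestChIP:
    def _records(self, loci, bound, inp, intergenic):
        return pd.DataFrame({"locus": loci, "bound": bound, "input": inp,
                             "is_intergenic": intergenic})

    def test_locus_matching_intergenic_ratio_is_one(self):
        rec = self._records(["gli1", "ig1"], [4.0, 2.0], [2.0, 1.0], [False, True])
        assert assayfit.chip_enrichment(rec)["gli1"] == pytest.approx(1.0)

    def test_linear_in_bound_signal(self):
        rec = self._records(["gli1", "gli1x2", "ig1"], [4.0, 8.0, 2.0],
                            [2.0, 2.0, 1.0], [False, False, True])
        out = assayfit.chip_enrichment(rec)
        assert out["gli1x2"] == pytest.approx(2 * out["gli1"])

    def test_matches_arithmetic_oracle(self, rng):
        n = 8
        rec = self._records([f"L{i}" for i in range(n)], rng.uniform(1, 10, n),
                            rng.uniform(1, 5, n), [False] * 5 + [True] * 3)
        out = assayfit.chip_enrichment(rec)
        ratio = rec["bound"] / rec["input"]
        norm = ratio[5:].mean()
        for i in range(n):
            assert out.iloc[i] == pytest.approx(ratio[i] / norm)

    def test_zero_input_errors(self):
        rec = self._records(["a", "ig"], [1.0, 1.0], [0.0, 1.0], [False, True])
        with pytest.raises(ValueError, match="input"):
            assayfit.chip_enrichment(rec)

    def test_no_intergenic_controls_errors(self):
        rec = self._records(["a"], [1.0], [1.0], [False])
        with pytest.raises(ValueError, match="intergenic"):
            assayfit.chip_enrichment(rec)
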