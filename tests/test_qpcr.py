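"""Standard curves, percent input, fold vs wt, relative copy number."""

import math

import numpy as np
import pandas as pd
import pytest

from telopirna.qpcr import (
    ChIPResult,
    copy_number,
    fit_efficiency,
    fold_vs_wt,
    percent_input,
)
from telopirna.simulate import generate_qpcr_plate


class TestFitEfficiency:
    def test_perfect_tenfold_series_gives_efficiency_two(self):
        # ct = intercept + slope * log10_dilution with slope -log2(10)
        slope = -math.log2(10)  # -3.3219...
        points = [(-float(i), 20.0 + slope * -float(i)) for i in range(4)]
        curve = fit_efficiency(points)
        assert curve.efficiency == pytest.approx(2.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)
        # successive Cts differ by exactly log2(10)
        assert points[1][1] - points[0][1] == pytest.approx(3.321928, abs=1e-6)

    def test_slope_minus_3_5(self):
        # ct rises by 3.5 per ten-fold dilution step
        points = [(-float(i), 20.0 + 3.5 * i) for i in range(4)]
        curve = fit_efficiency(points)
        assert curve.slope == pytest.approx(-3.5)
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.5), abs=1e-9)

    def test_positive_slope_rejected(self):
        points = [(-float(i), 20.0 - 3.3 * i) for i in range(4)]
        with pytest.raises(ValueError, match="slope"):
            fit_efficiency(points)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_efficiency([(0.0, 20.0), (-1.0, 23.3)])

    def test_recovery_from_noisy_plate(self):
        quantities = pd.DataFrame(
            [{"sample": "s", "primer_pair": "p", "role": "target", "quantity": 1.0}]
        )
        _, dil = generate_qpcr_plate(
            quantities, {"p": 1.9}, noise_sd=0.1, n_replicates=3, seed=5
        )
        curve = fit_efficiency(dil, "p")
        assert curve.efficiency == pytest.approx(1.9, abs=0.05)

    def test_recovery_unbiased_over_100_plates(self):
        quantities = pd.DataFrame(
            [{"sample": "s", "primer_pair": "p", "role": "target", "quantity": 1.0}]
        )
        errs = []
        for seed in range(100):
            _, dil = generate_qpcr_plate(
                quantities, {"p": 1.9}, noise_sd=0.1, seed=seed
            )
            errs.append(fit_efficiency(dil, "p").efficiency - 1.9)
        assert abs(np.mean(errs)) / 1.9 < 0.01


class TestPercentInput:
    def test_closed_form(self):
        r = percent_input([25.0], [20.0], efficiency=2.0, input_fraction=1.0)
        assert r.percent_input == pytest.approx(100 * 2 ** (20 - 25), rel=1e-12)
        assert r.percent_input == pytest.approx(3.125, rel=1e-12)

    def test_equal_cts_full_input_is_100_percent(self):
        r = percent_input([20.0, 20.0], [20.0, 20.0], 2.0, 1.0)
        assert r.percent_input == pytest.approx(100.0, rel=1e-12)

    def test_closed_form_with_fraction_and_odd_efficiency(self):
        # independent closed form: % = 100 * f * E**(ct_in - ct_ip)
        E, f = 1.9, 0.01
        r = percent_input([26.0], [24.0], E, f)
        assert r.percent_input == pytest.approx(100 * f * E ** (24 - 26), rel=1e-12)

    def test_input_fraction_exactness(self):
        # E**log_E(x) == x: halving the input fraction halves the result
        a = percent_input([25.0], [20.0], 2.0, 1.0).percent_input
        b = percent_input([25.0], [20.0], 2.0, 0.5).percent_input
        assert b == pytest.approx(a / 2, rel=1e-12)

    def test_strictly_decreasing_in_ip_ct(self):
        vals = [
            percent_input([ct], [20.0], 1.87, 0.05).percent_input
            for ct in np.linspace(18, 30, 25)
        ]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_replicates_averaged_on_ct_scale(self):
        r = percent_input([24.0, 26.0], [20.0], 2.0, 1.0)
        assert r.percent_input == pytest.approx(100 * 2 ** (20 - 25), rel=1e-12)
        assert r.sd > 0

    def test_nondetect_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="non-detect"):
            r = percent_input([25.0, 44.0], [20.0], 2.0, 1.0)
        assert r.percent_input == pytest.approx(3.125, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            percent_input([25.0], [20.0], 2.0, 0.0)
        with pytest.raises(ValueError):
            percent_input([25.0], [20.0], 1.0, 1.0)


class TestFoldVsWt:
    def make(self, sample, pct):
        return ChIPResult(sample, "HeTA", pct, 0.1)

    def test_half(self):
        df = fold_vs_wt([self.make("wt", 3.0), self.make("mut", 1.5)])
        assert df.set_index("sample").loc["mut", "fold_vs_wt"] == pytest.approx(0.5)

    def test_identity(self):
        df = fold_vs_wt([self.make("wt", 3.0), self.make("mut", 3.0)])
        assert df.set_index("sample").loc["mut", "fold_vs_wt"] == pytest.approx(1.0)

    def test_missing_wt_is_error(self):
        with pytest.raises(ValueError, match="wild-type"):
            fold_vs_wt([self.make("mut", 1.5)])

    def test_planted_enrichment_recovered(self):
        """rhi-like 2x HOAP enrichment survives the generator round trip."""
        E, f = 1.95, 0.01
        quantities = pd.DataFrame(
            [
                {"sample": s, "primer_pair": "HeTA", "role": role,
                 "quantity": q}
                for s, role, q in [
                    ("wt", "ip", 0.03), ("wt", "input", f),
                    ("rhi", "ip", 0.06), ("rhi", "input", f),
                ]
            ]
        )
        ct, dil = generate_qpcr_plate(quantities, {"HeTA": E}, noise_sd=0.05, seed=8)
        curve = fit_efficiency(dil, "HeTA")
        results = []
        for sample in ("wt", "rhi"):
            grp = ct[ct["sample"] == sample]
            results.append(
                percent_input(
                    grp.loc[grp.role == "ip", "ct"],
                    grp.loc[grp.role == "input", "ct"],
                    curve.efficiency, f, sample=sample, primer_pair="HeTA",
                )
            )
        df = fold_vs_wt(results)
        assert df.set_index("sample").loc["rhi", "fold_vs_wt"] == pytest.approx(
            2.0, rel=0.15
        )


class TestCopyNumber:
    def test_identical_delta_ct_gives_fold_one(self):
        res = copy_number(
            {"test": [22.0], "control": [24.0]},
            {"test": [20.0], "control": [22.0]},
            2.0, 2.0, "control",
        )
        folds = {r.sample: r.fold_vs_control for r in res}
        assert folds["test"] == pytest.approx(1.0, rel=1e-12)

    def test_log2_12_shift_gives_fold_12(self):
        shift = math.log2(12)
        res = copy_number(
            {"test": [24.0 - shift], "control": [24.0]},
            {"test": [20.0], "control": [20.0]},
            2.0, 2.0, "control",
        )
        folds = {r.sample: r.fold_vs_control for r in res}
        assert folds["test"] == pytest.approx(12.0, rel=1e-12)

    def test_equals_ddct_closed_form(self):
        # with both efficiencies 2 the result is exactly 2**(-ddCt)
        t = {"test": [23.1], "control": [25.7]}
        r = {"test": [19.4], "control": [20.2]}
        res = copy_number(t, r, 2.0, 2.0, "control")
        ddct = (t["test"][0] - r["test"][0]) - (t["control"][0] - r["control"][0])
        folds = {x.sample: x.fold_vs_control for x in res}
        assert folds["test"] == pytest.approx(2 ** (-ddct), rel=1e-12)

    def test_missing_control_is_error(self):
        with pytest.raises(ValueError, match="control"):
            copy_number({"a": [20.0]}, {"a": [20.0]}, 2.0, 2.0, "zzz")

    @staticmethod
    def recover_fold(planted: float, noise_sd: float, seed: int) -> float:
        quantities = pd.DataFrame(
            [
                {"sample": "gaiano", "primer_pair": "HeTA", "role": "target", "quantity": planted},
                {"sample": "control", "primer_pair": "HeTA", "role": "target", "quantity": 1.0},
                {"sample": "gaiano", "primer_pair": "Rp49", "role": "reference", "quantity": 1.0},
                {"sample": "control", "primer_pair": "Rp49", "role": "reference", "quantity": 1.0},
            ]
        )
        ct, _ = generate_qpcr_plate(
            quantities, {"HeTA": 2.0, "Rp49": 2.0}, noise_sd=noise_sd, seed=seed
        )
        target = {
            s: g["ct"].tolist()
            for s, g in ct[ct.primer_pair == "HeTA"].groupby("sample")
        }
        ref = {
            s: g["ct"].tolist()
            for s, g in ct[ct.primer_pair == "Rp49"].groupby("sample")
        }
        res = copy_number(target, ref, 2.0, 2.0, "control")
        return {r.sample: r.fold_vs_control for r in res}["gaiano"]

    def test_planted_12x_recovered_with_noise(self):
        """Recovery of a planted 12-fold copy excess at Ct noise sd 0.1.

        A single triplicate plate carries ~8% multiplicative sampling sd
        (four Ct means, 0.1 cycles each), so a per-plate +-10% check would
        fail by chance one run in five; the geometric mean over 20
        independent plates pins the recovered fold to well within 10%.
        """
        folds = [self.recover_fold(12.0, 0.1, seed) for seed in range(20)]
        geo_mean = float(np.exp(np.mean(np.log(folds))))
        assert geo_mean == pytest.approx(12.0, rel=0.10)

    def test_planted_12x_exact_without_noise(self):
        assert self.recover_fold(12.0, 0.0, 0) == pytest.approx(12.0, rel=1e-9)
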