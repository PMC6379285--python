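"""Agreement statistics: Lin's CCC, RMA regression, percent Bland-Altman,
and the threshold-calibration sweep."""

import math

import numpy as np
import pytest
from scipy import stats

from sitvolumetry import (
    MethodAgreement,
    NoduleSpec,
    PhantomSpec,
    SphericalROI,
    ThresholdCalibration,
    bland_altman_percent,
    calibrate_threshold,
    compose_phantom,
    lin_ccc,
    mask_volume,
    rma_fit,
    segment_sit,
)


def ccc_oracle(x, y):
    """Direct evaluation of the moment formula with plain Python."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx2 = sum((v - mx) ** 2 for v in x) / n
    sy2 = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    rho = sxy / math.sqrt(sx2 * sy2)
    rho_c = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    return rho, rho_c / rho, rho_c


class TestLinCcc:
    def test_perfect_concordance(self):
        x = [50.0, 100.0, 200.0, 400.0]
        cc = lin_ccc(x, x)
        assert cc.rho == pytest.approx(1.0)
        assert cc.c_b == pytest.approx(1.0)
        assert cc.rho_c == pytest.approx(1.0)

    def test_location_shift_penalized(self):
        x = np.array([50.0, 100.0, 200.0, 400.0])
        cc = lin_ccc(x, x + 30.0)
        assert cc.rho == pytest.approx(1.0)
        assert cc.c_b < 1.0
        assert cc.rho_c == pytest.approx(cc.rho * cc.c_b)
        assert cc.rho_c < 1.0

    def test_matches_moment_formula_oracle(self):
        x = [50.0, 100.0, 200.0, 400.0]
        y = [55.0, 95.0, 210.0, 380.0]
        cc = lin_ccc(x, y)
        rho, c_b, rho_c = ccc_oracle(x, y)
        assert cc.rho == pytest.approx(rho, rel=1e-12)
        assert cc.c_b == pytest.approx(c_b, rel=1e-12)
        assert cc.rho_c == pytest.approx(rho_c, rel=1e-12)

    def test_pearson_component_matches_scipy(self, rng):
        x = rng.uniform(10, 500, 25)
        y = x * 1.1 + rng.normal(0, 20, 25)
        assert lin_ccc(x, y).rho == pytest.approx(stats.pearsonr(x, y)[0], rel=1e-12)

    def test_rho_c_bounded_by_rho(self, rng):
        for _ in range(20):
            x = rng.uniform(10, 500, 15)
            y = x + rng.normal(10, 30, 15)
            cc = lin_ccc(x, y)
            assert abs(cc.rho_c) <= abs(cc.rho) + 1e-12 <= 1.0 + 1e-12

    @pytest.mark.parametrize("a", [0.5, 2.0, 97.0])
    def test_scale_invariance(self, rng, a):
        x = rng.uniform(10, 500, 12)
        y = x + rng.normal(0, 25, 12)
        cc = lin_ccc(x, y)
        cc2 = lin_ccc(a * x, a * y)
        assert cc2.rho_c == pytest.approx(cc.rho_c, rel=1e-10)
        assert cc2.c_b == pytest.approx(cc.c_b, rel=1e-10)

    def test_constant_vector_signaled(self):
        with pytest.raises(ValueError, match="constant"):
            lin_ccc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            lin_ccc([1.0, 2.0], [1.0, 2.0])  # n < 3

    def test_sample_moment_variant(self, rng):
        x = rng.uniform(10, 500, 10)
        y = x + rng.normal(0, 25, 10)
        # rho is moment-count invariant; rho_c differs between variants
        assert lin_ccc(x, y, ddof=1).rho == pytest.approx(lin_ccc(x, y).rho)
        assert lin_ccc(x, y, ddof=1).rho_c != lin_ccc(x, y).rho_c


class TestRma:
    def test_proportional_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = rma_fit(x, 2.0 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0)

    def test_line_of_equality(self):
        x = np.array([10.0, 20.0, 40.0])
        fit = rma_fit(x, x)
        assert (fit.slope, fit.intercept) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_slope_squared_is_variance_ratio(self, rng):
        x = rng.uniform(0, 100, 30)
        y = 3.0 * x + rng.normal(0, 10, 30)
        fit = rma_fit(x, y)
        assert fit.slope**2 == pytest.approx(y.var() / x.var(), rel=1e-10)
        assert fit.slope > 0  # sign of rho

    def test_negative_correlation_gives_negative_slope(self, rng):
        x = rng.uniform(0, 100, 30)
        y = -2.0 * x + rng.normal(0, 5, 30)
        assert rma_fit(x, y).slope < 0

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            rma_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_uniform_ten_percent_offset(self):
        x = np.array([100.0, 200.0, 300.0])
        ba = bland_altman_percent(x, 1.10 * x)
        assert ba.bias == pytest.approx(10.0)
        assert ba.sd == pytest.approx(0.0, abs=1e-12)
        assert ba.loa_low == pytest.approx(10.0)
        assert ba.loa_high == pytest.approx(10.0)

    def test_identity_all_zero(self):
        x = np.array([100.0, 200.0, 300.0])
        ba = bland_altman_percent(x, x)
        assert (ba.bias, ba.sd, ba.loa_low, ba.loa_high) == (0, 0, 0, 0)

    def test_hand_computation(self):
        # d = {2, -2, 4}: bias 4/3, sample sd sqrt(28/3)
        ba = bland_altman_percent([100.0, 200.0, 300.0], [102.0, 196.0, 312.0])
        bias = (2.0 - 2.0 + 4.0) / 3.0
        sd = math.sqrt(((2 - bias) ** 2 + (-2 - bias) ** 2 + (4 - bias) ** 2) / 2.0)
        assert ba.bias == pytest.approx(bias, rel=1e-12)
        assert ba.sd == pytest.approx(sd, rel=1e-12)
        assert ba.loa_low == pytest.approx(bias - 1.96 * sd, rel=1e-12)
        assert ba.loa_high == pytest.approx(bias + 1.96 * sd, rel=1e-12)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            bland_altman_percent([100.0, 0.0, 300.0], [1.0, 2.0, 3.0])

    def test_loa_invariant(self, rng):
        x = rng.uniform(50, 500, 20)
        y = x * rng.uniform(0.8, 1.2, 20)
        ba = bland_altman_percent(x, y)
        assert ba.loa_low == pytest.approx(ba.bias - 1.96 * ba.sd)
        assert ba.loa_high == pytest.approx(ba.bias + 1.96 * ba.sd)


def _calibration_cases(n=6, seed=0):
    """Blurred noiseless phantoms spanning a range of volumes."""
    cases = []
    rng = np.random.default_rng(seed)
    for i, v in enumerate(np.linspace(80.0, 500.0, n)):
        nod = NoduleSpec(f"n{i}", (14.0, 14.0, 14.0), float(v), "hemisphere")
        spec = PhantomSpec(
            grid_shape=(29, 29, 29), spacing=(1.0, 1.0, 1.0), nodules=[nod],
            nodule_signal=100.0, background_mean=0.0, blur_fwhm=1.5,
            noise_sd=0.0, supersample=4, seed=int(rng.integers(2**31)),
        )
        image, _ = compose_phantom(spec)
        cases.append((image, SphericalROI(nod.center, 12.5), nod.volume_true))
    return cases


class TestCalibration:
    def test_planted_optimum_recovered(self):
        cases = _calibration_cases()
        # replace truths by the volume each case measures at C = 0.30:
        # concordance at 0.30 is then exactly 1 and the sweep must select it
        planted = [
            (img, roi, mask_volume(segment_sit(img, roi, 0.30)))
            for img, roi, _ in cases
        ]
        table, selected, errors = calibrate_threshold(planted)
        assert errors == []
        assert selected == 0.30
        row = table.loc[table["c"] == 0.30].iloc[0]
        assert row["rho_c"] == pytest.approx(1.0)

    def test_table_rows_reproduce_individual_ccc_calls(self):
        cases = _calibration_cases()
        table, _, _ = calibrate_threshold(cases)
        truths = [c[2] for c in cases]
        for _, row in table.iterrows():
            vols = [mask_volume(segment_sit(img, roi, row["c"]))
                    for img, roi, _ in cases]
            cc = lin_ccc(truths, vols)
            assert row["rho_c"] == pytest.approx(cc.rho_c, rel=1e-12)
            assert row["rho"] == pytest.approx(cc.rho, rel=1e-12)

    def test_volume_non_increasing_in_c(self):
        for img, roi, _ in _calibration_cases(n=4):
            vols = [mask_volume(segment_sit(img, roi, c))
                    for c in (0.20, 0.30, 0.40, 0.50)]
            assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_tie_breaks_toward_smaller_c(self, binary_phantom):
        image, roi, nod = binary_phantom
        # binary image: identical volumes (hence identical rho_c) at every C
        cases = []
        for dv in (0.7, 1.0, 1.3):
            n2 = NoduleSpec("n", nod.center, nod.volume_true * dv, "sphere")
            spec = PhantomSpec(
                grid_shape=(29, 29, 29), spacing=(1.0, 1.0, 1.0), nodules=[n2],
                nodule_signal=100.0, supersample=1, seed=2,
            )
            img2, _ = compose_phantom(spec)
            cases.append((img2, roi, n2.volume_true))
        table, selected, _ = calibrate_threshold(cases)
        assert len(set(np.round(table["rho_c"], 12))) == 1
        assert selected == 0.20

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(_calibration_cases(n=2))


class TestModelObjects:
    def test_method_agreement_results(self, rng):
        x = rng.uniform(50, 500, 18)
        y = x * 1.02 + rng.normal(0, 10, 18)
        res = MethodAgreement(x, y, xname="truth", yname="mri").fit()
        assert res.nobs == 18
        d = res.to_dict()
        assert d["rho_c"] == pytest.approx(lin_ccc(x, y).rho_c)
        assert d["bias_pct"] == pytest.approx(bland_altman_percent(x, y).bias)
        text = res.summary()
        assert "mri vs truth" in text
        assert "rho_c" in text

    def test_threshold_calibration_model(self):
        res = ThresholdCalibration(_calibration_cases(n=4)).fit()
        assert set(res.table["c"]) == {0.20, 0.30, 0.40, 0.50}
        assert res.selected_c in set(res.table["c"])
        assert "selected C" in res.summary()

    def test_plots_return_axes(self, rng, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        x = rng.uniform(50, 500, 10)
        y = x * 1.05 + rng.normal(0, 15, 10)
        res = MethodAgreement(x, y).fit()
        ax1 = res.plot_concordance()
        ax2 = res.plot_bland_altman()
        ax1.figure.savefig(tmp_path / "cc.png")
        ax2.figure.savefig(tmp_path / "ba.png")
        assert (tmp_path / "cc.png").exists()
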