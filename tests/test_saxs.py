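"""Composite SAXS model evaluation, I/O, and fitting."""

import numpy as np
import pytest

from coacervkit.saxs import (
    SAXSCurve,
    SAXSModelParams,
    composite_intensity,
    fit_saxs,
    gg_coil_intensity,
    peak_structure_factor,
    porod_term,
    read_saxs_ascii,
    write_saxs_ascii,
)
from coacervkit.synthetic import gen_saxs


def debye_function(x):
    """Closed-form Gaussian-chain form factor: independent oracle for nu=0.5."""
    return 2.0 * (np.exp(-x) - 1.0 + x) / x**2


class TestReader:
    def test_three_column_file(self, tmp_path):
        path = tmp_path / "c.dat"
        q = np.linspace(0.01, 0.4, 100)
        np.savetxt(path, np.column_stack([q, np.ones(100), 0.02 * np.ones(100)]))
        curve = read_saxs_ascii(path)
        assert curve.q.size == 100
        assert curve.sigma is not None

    def test_header_comment_skipped(self, tmp_path):
        path = tmp_path / "c.dat"
        body = "\n".join(f"{0.01 * (i + 1)} 1.0 0.1" for i in range(12))
        path.write_text("# q I err\n" + body + "\n")
        assert read_saxs_ascii(path).q.size == 12

    def test_comma_separated(self, tmp_path):
        path = tmp_path / "c.csv"
        body = "\n".join(f"{0.01 * (i + 1)},1.0" for i in range(12))
        path.write_text(body)
        curve = read_saxs_ascii(path)
        assert curve.sigma is None

    def test_negative_q_names_line(self, tmp_path):
        path = tmp_path / "c.dat"
        rows = [f"{0.01 * (i + 1)} 1.0" for i in range(12)]
        rows[4] = "-0.05 1.0"
        path.write_text("\n".join(rows))
        with pytest.raises(ValueError, match="line 5"):
            read_saxs_ascii(path)

    def test_single_column_rejected(self, tmp_path):
        path = tmp_path / "c.dat"
        path.write_text("\n".join(str(0.01 * (i + 1)) for i in range(12)))
        with pytest.raises(ValueError, match="2 columns"):
            read_saxs_ascii(path)

    def test_write_read_round_trip(self, tmp_path):
        curve, _ = gen_saxs(seed=0)
        path = tmp_path / "rt.dat"
        write_saxs_ascii(curve, path)
        back = read_saxs_ascii(path)
        assert np.allclose(back.q, curve.q)
        assert np.allclose(back.intensity, curve.intensity)

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError, match="10"):
            SAXSCurve(q=np.linspace(0.01, 0.1, 5), intensity=np.ones(5))


class TestCoilFormFactor:
    def test_normalization_at_low_q(self):
        val = gg_coil_intensity(np.array([1e-6]), 10.0, 0.4, scale=3.0, background=0.5)
        assert val[0] == pytest.approx(3.5, rel=1e-6)

    def test_debye_limit_at_nu_half(self):
        rg = 9.23
        q = np.logspace(np.log10(0.01), np.log10(10.0), 300) / rg
        p = gg_coil_intensity(q, rg, 0.5)
        x = q**2 * rg**2
        assert np.max(np.abs(p - debye_function(x)) / debye_function(x)) < 1e-6

    def test_guinier_regime(self):
        rg = 18.95
        q = np.linspace(0.001, 0.29 / rg, 30)
        p = gg_coil_intensity(q, rg, 0.4)
        guinier = 1.0 - q**2 * rg**2 / 3.0
        assert np.max(np.abs(p - guinier) / guinier) < 0.01

    @pytest.mark.parametrize("nu", [0.3, 0.5, 0.7, 1.0])
    def test_positive_and_monotone_nonincreasing(self, nu):
        q = np.logspace(-3, 0.5, 200)
        p = gg_coil_intensity(q, 10.0, nu)
        assert np.all(p > 0)
        assert np.all(np.diff(p) <= 1e-12)


class TestPorodAndPeak:
    def test_loglog_slope(self):
        q = np.array([0.01, 0.02])
        i = porod_term(q, 2.0, 4.0)
        slope = np.diff(np.log(i)) / np.diff(np.log(q))
        assert slope[0] == pytest.approx(-4.0, rel=1e-12)

    def test_doubling_q_at_n4(self):
        assert porod_term(np.array([0.02]), 1.0, 4.0)[0] == pytest.approx(
            porod_term(np.array([0.01]), 1.0, 4.0)[0] / 16.0
        )

    def test_peak_factor_shape(self):
        q = np.linspace(0.01, 0.3, 100)
        s = peak_structure_factor(q, 0.5, 0.1, 50.0)
        assert s[np.argmin(np.abs(q - 0.1))] == pytest.approx(1.5, abs=1e-3)
        assert s[-1] < 1.05
        assert np.all(peak_structure_factor(q, 0.0, 0.1, 50.0) == 1.0)


class TestComposite:
    def test_background_only(self):
        params = SAXSModelParams(coil_scale=0.0, background=0.7)
        q = np.logspace(-2, 0, 50)
        assert np.allclose(composite_intensity(q, params, "coacervate"), 0.7)

    def test_low_q_porod_slope(self):
        params = SAXSModelParams(
            coil_scale=1.0, rg=9.23, nu=0.4, porod_amplitude=1e-8, porod_exponent=4.0
        )
        q = np.array([4e-4, 5e-4])  # power-law term dominates far below 1/Rg
        i = composite_intensity(q, params, "coacervate")
        slope = np.diff(np.log(i)) / np.diff(np.log(q))
        assert slope[0] == pytest.approx(-4.0, abs=0.01)

    def test_additivity(self):
        params = SAXSModelParams(
            coil_scale=1.0, rg=9.23, nu=0.4, porod_amplitude=1e-8, background=0.01
        )
        q = np.logspace(np.log10(0.004), np.log10(0.4), 50)
        total = composite_intensity(q, params, "coacervate")
        parts = (
            porod_term(q, params.porod_amplitude, params.porod_exponent)
            + gg_coil_intensity(q, params.rg, params.nu, params.coil_scale)
            + params.background
        )
        assert np.allclose(total, parts, rtol=1e-12)

    def test_monomer_variant_uses_peak(self):
        params = SAXSModelParams(
            coil_scale=1.0, rg=9.23, nu=0.4, background=0.0,
            peak_amplitude=0.5, peak_position=0.1, peak_width=50.0,
        )
        q = np.logspace(np.log10(0.004), np.log10(0.4), 200)
        i = composite_intensity(q, params, "monomer")
        coil = gg_coil_intensity(q, params.rg, params.nu)
        assert np.max(i / coil) > 1.2  # peak enhancement visible


class TestFit:
    def test_noise_free_fixed_point(self):
        truth = SAXSModelParams(
            coil_scale=1.0, rg=9.23, nu=0.4, porod_amplitude=1e-8,
            porod_exponent=4.0, background=0.01,
        )
        curve, _ = gen_saxs(seed=0, truth=truth, noise=0.0)
        res = fit_saxs(curve, "coacervate", init=truth, fixed={"porod_exponent"})
        assert res.params.rg == pytest.approx(truth.rg, rel=1e-8)
        assert res.params.nu == pytest.approx(truth.nu, rel=1e-8)
        assert res.params.coil_scale == pytest.approx(truth.coil_scale, rel=1e-8)

    @pytest.mark.parametrize("rg_true", [9.23, 18.95])
    def test_rg_recovery_under_noise(self, rg_true):
        truth = SAXSModelParams(
            coil_scale=1.0, rg=rg_true, nu=0.4, porod_amplitude=1e-8,
            porod_exponent=4.0, background=0.01,
        )
        recovered = []
        for seed in range(20):
            curve, _ = gen_saxs(seed=seed, truth=truth, noise=0.02)
            init = SAXSModelParams(
                coil_scale=1.5, rg=rg_true * 1.5, nu=0.6,
                porod_amplitude=1.5e-8, porod_exponent=4.0, background=0.015,
            )
            res = fit_saxs(curve, "coacervate", init=init, fixed={"porod_exponent"})
            recovered.append(res.params.rg)
        median = float(np.median(recovered))
        assert abs(median - rg_true) / rg_true < 0.02

    def test_chi_square_descends_from_init(self):
        truth = SAXSModelParams(
            coil_scale=1.0, rg=9.23, nu=0.4, porod_amplitude=1e-8, background=0.01
        )
        curve, _ = gen_saxs(seed=3, truth=truth, noise=0.02)
        init = SAXSModelParams(
            coil_scale=2.0, rg=15.0, nu=0.5, porod_amplitude=2e-8, background=0.02
        )
        model0 = composite_intensity(curve.q, init, "coacervate")
        chi0 = np.sum(((model0 - curve.intensity) / curve.sigma) ** 2)
        res = fit_saxs(curve, "coacervate", init=init, fixed={"porod_exponent"})
        ndata = curve.q.size
        nvary = len(res.stderr)
        assert res.redchi * (ndata - nvary) <= chi0

    def test_intensity_rescaling_covariance(self):
        truth = SAXSModelParams(
            coil_scale=1.0, rg=9.23, nu=0.4, porod_amplitude=1e-8, background=0.01
        )
        curve, _ = gen_saxs(seed=5, truth=truth, noise=0.02)
        k = 7.5
        scaled = SAXSCurve(curve.q, k * curve.intensity, k * curve.sigma)
        init = SAXSModelParams(
            coil_scale=1.4, rg=12.0, nu=0.5, porod_amplitude=1.4e-8, background=0.014
        )
        init_k = SAXSModelParams(
            coil_scale=1.4 * k, rg=12.0, nu=0.5,
            porod_amplitude=1.4e-8 * k, background=0.014 * k,
        )
        r1 = fit_saxs(curve, "coacervate", init=init, fixed={"porod_exponent"})
        r2 = fit_saxs(scaled, "coacervate", init=init_k, fixed={"porod_exponent"})
        assert r2.params.rg == pytest.approx(r1.params.rg, rel=1e-6)
        assert r2.params.nu == pytest.approx(r1.params.nu, rel=1e-6)
        assert r2.params.coil_scale == pytest.approx(k * r1.params.coil_scale, rel=1e-6)

    def test_monomer_variant_fit(self):
        truth = SAXSModelParams(
            coil_scale=1.0, rg=9.23, nu=0.4, background=0.01,
            peak_amplitude=0.5, peak_position=0.1, peak_width=50.0,
        )
        curve, _ = gen_saxs(seed=2, truth=truth, variant="monomer", noise=0.01)
        init = SAXSModelParams(
            coil_scale=1.2, rg=11.0, nu=0.45, background=0.012,
            peak_amplitude=0.4, peak_position=0.11, peak_width=40.0,
        )
        res = fit_saxs(curve, "monomer", init=init, fixed={"peak_shape"})
        assert res.params.rg == pytest.approx(9.23, rel=0.05)
        assert res.params.peak_position == pytest.approx(0.1, rel=0.05)
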