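"""Transmural cable construction, Brugada parameterization, pseudo-ECG
and the deviation score."""

import numpy as np
import pytest

from bacnavsim.brugada import (
    SEVERITIES,
    BrugadaSeverity,
    EcgTrace,
    LayerSpec,
    TransmuralSpec,
    apply_brugada,
    build_transmural_cable,
    ecg_deviation,
    pseudo_ecg,
)
from bacnavsim.errors import (
    AlignmentError,
    InvalidInputError,
    SingularGeometryError,
)
from bacnavsim.fixtures import gaussian_wave
from bacnavsim.models import get_model

NAMES = get_model("guineapig").param_names


def _p(cable, name, cell_1based):
    return cable.params[NAMES.index(name), cell_1based - 1]


class TestTransmuralConstruction:
    def test_layer_sizes_are_exact(self):
        spec = TransmuralSpec()
        assert [l.n_cells for l in spec.layers] == [60, 45, 60]
        assert spec.n_cells_total == 165
        assert spec.layer_of(60).name == "endo"
        assert spec.layer_of(61).name == "mid"
        assert spec.layer_of(105).name == "mid"
        assert spec.layer_of(106).name == "epi"

    def test_printed_layer_parameters_applied(self):
        cable = build_transmural_cable()
        assert _p(cable, "g_to", 30) == 0.0            # endocardium
        assert _p(cable, "g_to", 80) == pytest.approx(0.2125)   # mid
        assert _p(cable, "g_to", 150) == pytest.approx(0.25)    # epi
        # IKs:IKr conductance ratios are exact per layer
        assert _p(cable, "g_Ks", 30) / _p(cable, "g_Kr", 30) == \
            pytest.approx(11.0)
        assert _p(cable, "g_Ks", 80) / _p(cable, "g_Kr", 80) == \
            pytest.approx(4.0)
        assert _p(cable, "g_Ks", 150) / _p(cable, "g_Kr", 150) == \
            pytest.approx(35.0)

    def test_invalid_layer_sum_rejected(self):
        with pytest.raises(InvalidInputError):
            TransmuralSpec(layers=(
                LayerSpec("endo", 60, 0.0, 11.0),
                LayerSpec("mid", 45, 0.2125, 4.0),
                LayerSpec("epi", 59, 0.25, 35.0),
            ))

    def test_bacnav_requires_gbar(self):
        with pytest.raises(InvalidInputError):
            build_transmural_cable(x_level=0.5)


class TestApplyBrugada:
    def test_identity_severity_is_bitwise_noop(self):
        cable = build_transmural_cable()
        out = apply_brugada(cable, BrugadaSeverity(1.0, 1.0))
        assert np.array_equal(out.params, cable.params, equal_nan=True)

    def test_mild_epicardial_ito_arithmetic(self):
        cable = apply_brugada(build_transmural_cable(), SEVERITIES["mild"])
        assert _p(cable, "g_to", 150) == pytest.approx(0.75)    # 0.25 * 3
        assert _p(cable, "h_speed", 10) == pytest.approx(1.5)

    def test_severe_factors(self):
        sev = SEVERITIES["severe"]
        assert (sev.inactivation_speed, sev.ito_multiplier) == (3.5, 7.0)
        cable = apply_brugada(build_transmural_cable(), sev)
        assert _p(cable, "g_to", 150) == pytest.approx(1.75)

    def test_sub_unity_factors_rejected(self):
        with pytest.raises(InvalidInputError):
            BrugadaSeverity(0.5, 1.0)


class TestPseudoEcg:
    def test_uniform_field_gives_zero(self):
        t = np.arange(100.0)
        x = (np.arange(165) + 0.5) * 0.01
        vm = np.full((165, 100), -70.0) + 10.0 * np.sin(t / 30.0)[None, :]
        ecg = pseudo_ecg(t, vm, x, x[-1] + 2.0)
        assert np.allclose(ecg.phi_e, 0.0, atol=1e-15)

    def test_linearity_in_vm(self):
        t, vm, x = gaussian_wave()
        e1 = pseudo_ecg(t, vm, x, x[-1] + 2.0)
        e3 = pseudo_ecg(t, 3.0 * vm, x, x[-1] + 2.0)
        assert np.allclose(e3.phi_e, 3.0 * e1.phi_e, rtol=1e-12)

    def test_matches_fine_quadrature_of_gaussian_wave(self):
        """Independent oracle: the integrand of the line-source integral
        has a closed-form spatial derivative for the Gaussian wave;
        integrate it on a 20x finer grid with the trapezoid rule."""
        t, vm, x = gaussian_wave(n_x=165, n_t=120)
        xe = x[-1] + 2.0
        ecg = pseudo_ecg(t, vm, x, xe)

        width, amp, speed, c0 = 0.15, 100.0, 0.04, 0.4
        xf = np.linspace(x[0], x[-1], 165 * 20)
        phi_ref = np.empty_like(t)
        for k, tk in enumerate(t):
            c = c0 + speed * tk
            dvdx = amp * np.exp(-((xf - c) ** 2) / (2 * width ** 2)) \
                * (-(xf - c) / width ** 2)
            dinv = 1.0 / (xe - xf) ** 2           # d(1/r)/dx on axis
            phi_ref[k] = (1e-3 ** 2 / 4.0) * np.trapezoid(-dvdx * dinv, xf)
        # compare while the wave is fully interior: once it reaches the
        # fiber end nearest the electrode, boundary truncation (one-sided
        # vs trapezoid edge handling) dominates both discretizations
        interior = (c0 + speed * t) <= (x[-1] - 3 * width)
        scale = np.max(np.abs(phi_ref[interior]))
        assert np.max(np.abs(ecg.phi_e - phi_ref)[interior]) < 0.01 * scale

    def test_singular_electrode_rejected(self):
        t, vm, x = gaussian_wave(n_t=5)
        with pytest.raises(SingularGeometryError):
            pseudo_ecg(t, vm, x, float(x[80]))


class TestEcgDeviation:
    def _trace(self, values, t0=0.0):
        t = t0 + np.arange(len(values), dtype=float)
        return EcgTrace(t=t, phi_e=np.asarray(values, float),
                        electrode_cm=3.65)

    def test_self_deviation_is_zero(self):
        a = self._trace(np.sin(np.arange(300) / 20.0))
        assert ecg_deviation(a, a) == 0.0

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(7)
        a = self._trace(rng.normal(size=200))
        b = self._trace(rng.normal(size=200))
        c = self._trace(rng.normal(size=200))
        dab = ecg_deviation(a, b)
        assert dab == pytest.approx(ecg_deviation(b, a), rel=1e-12)
        assert dab <= ecg_deviation(a, c) + ecg_deviation(c, b) + 1e-12

    def test_disjoint_time_bases_rejected(self):
        a = self._trace(np.ones(50), t0=0.0)
        b = self._trace(np.ones(50), t0=1000.0)
        with pytest.raises(AlignmentError):
            ecg_deviation(a, b)
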