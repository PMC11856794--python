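import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cantibeat import beam_core as bc
from cantibeat.errors import ParameterError, SingularModeError


class TestSectionProperties:
    @pytest.mark.parametrize(
        "d, area, i_sec",
        [
            (2.0e-4, math.pi * 4e-8 / 4, math.pi * 1.6e-15 / 64),
            (2.0, math.pi, math.pi / 4),
        ],
    )
    def test_circular_section(self, d, area, i_sec):
        a, i = bc.section_properties(d)
        assert a == pytest.approx(area, rel=1e-12)
        assert i == pytest.approx(i_sec, rel=1e-12)

    def test_scaling_laws(self):
        a1, i1 = bc.section_properties(1e-4)
        a2, i2 = bc.section_properties(2e-4)
        assert a2 / a1 == pytest.approx(4.0, rel=1e-12)
        assert i2 / i1 == pytest.approx(16.0, rel=1e-12)

    @pytest.mark.parametrize("d", [0.0, -1.0])
    def test_invalid_diameter(self, d):
        with pytest.raises(ParameterError):
            bc.section_properties(d)


class TestCantileverSpec:
    def test_derived_quantities(self, stiff_spec):
        assert stiff_spec.area == pytest.approx(3.1416e-8, rel=1e-4)
        assert stiff_spec.second_moment == pytest.approx(7.854e-17, rel=1e-4)
        assert stiff_spec.flexural_rigidity == pytest.approx(
            stiff_spec.elastic_modulus * stiff_spec.second_moment, rel=1e-12
        )

    def test_json_roundtrip(self, tmp_path, stiff_spec):
        p = tmp_path / "spec.json"
        stiff_spec.to_json(p)
        assert bc.CantileverSpec.from_json(p) == stiff_spec

    @pytest.mark.parametrize(
        "kwargs", [{"length": -1.0}, {"diameter": 0.0}, {"density": -2.0}]
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ParameterError):
            bc.CantileverSpec(**{"length": 0.01, **kwargs})


class TestWavenumber:
    def test_zero_frequency(self, stiff_spec):
        assert bc.wavenumber(0.0, stiff_spec) == 0.0

    def test_silver_wire_value(self, stiff_spec):
        # direct evaluation of (rho A omega^2 / EI)^(1/4) at 1 Hz
        assert bc.wavenumber(2 * math.pi, stiff_spec) == pytest.approx(6.69, rel=1e-2)

    def test_square_root_scaling(self, stiff_spec):
        # k = (rho A omega^2 / EI)^(1/4) scales as omega^(1/2)
        k1 = bc.wavenumber(2.0, stiff_spec)
        k2 = bc.wavenumber(32.0, stiff_spec)
        assert k2 / k1 == pytest.approx(4.0, rel=1e-12)

    def test_negative_frequency_rejected(self, stiff_spec):
        with pytest.raises(ParameterError):
            bc.wavenumber(-1.0, stiff_spec)


class TestModalCoefficients:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        s=st.floats(1e-9, 1e-4),
        f_frac=st.floats(1e-4, 0.9),
        phi=st.floats(-3.0, 3.0),
    )
    def test_boundary_conditions_satisfied(self, s, f_frac, phi):
        """The assembled mode must satisfy the clamp (y=y'=0) and the tip
        (y=S, y''=0) conditions for any sub-resonance harmonic."""
        spec = bc.silver_wire()
        omega = 2 * math.pi * f_frac * spec.resonance_frequency_hz(1)
        mc = bc.modal_coefficients(s, omega, phi, spec)
        assert bc.mode_shape(mc, 0.0, 0) == 0.0
        assert bc.mode_shape(mc, 0.0, 1) == 0.0
        assert abs(bc.mode_shape(mc, spec.length, 0) - s) / s < 1e-9
        assert (
            abs(bc.mode_shape(mc, spec.length, 2)) * spec.length**2 / s < 1e-9
        )

    def test_zero_amplitude_gives_zero_coefficients(self, stiff_spec):
        mc = bc.modal_coefficients(0.0, 100.0, 0.0, stiff_spec)
        assert mc.c1 == 0.0 and mc.c2 == 0.0

    def test_wavenumber_increases_with_frequency(self, stiff_spec):
        ks = [
            bc.modal_coefficients(1e-6, om, 0.0, stiff_spec).wavenumber
            for om in (10.0, 100.0, 1000.0)
        ]
        assert ks == sorted(ks) and ks[0] > 0

    def test_resonant_harmonic_flagged(self, stiff_spec):
        f_res = stiff_spec.resonance_frequency_hz(1)
        with pytest.warns(RuntimeWarning, match="resonance"):
            mc = bc.modal_coefficients(1e-6, 2 * math.pi * f_res, 0.0, stiff_spec)
        assert mc.singular
        with pytest.raises(SingularModeError, match="Hz"):
            bc.tip_shear_amplitude(mc, stiff_spec)

    def test_large_kappa_stays_finite(self, stiff_spec):
        mc = bc.modal_coefficients(1e-6, 2 * math.pi * 5e6, 0.0, stiff_spec)
        assert np.isfinite(mc.c1) and np.isfinite(mc.c2)


class TestTipShear:
    def test_zero_amplitude(self, stiff_spec):
        mc = bc.modal_coefficients(0.0, 50.0, 0.0, stiff_spec)
        assert bc.tip_shear_amplitude(mc, stiff_spec) == 0.0

    def test_quasistatic_limit(self, stiff_spec):
        """kappa -> 0: tip shear approaches the static point-load relation
        3 EI S / L^3 (delta = P L^3 / 3EI)."""
        s = 1e-6
        static = 3 * stiff_spec.flexural_rigidity * s / stiff_spec.length**3
        omega = (1e-3 / stiff_spec.length) ** 2 * stiff_spec.wave_speed_factor()
        mc = bc.modal_coefficients(s, omega, 0.0, stiff_spec)
        assert bc.tip_shear_amplitude(mc, stiff_spec) == pytest.approx(
            static, rel=1e-4
        )

    def test_quasistatic_convergence_monotone(self, stiff_spec):
        """Shear/(3EI S/L^3) rises monotonically toward the dynamic regime
        over kappa in [1e-3, 0.3] — no spurious oscillation of the ratio."""
        s = 1e-6
        static = 3 * stiff_spec.flexural_rigidity * s / stiff_spec.length**3
        kappas = np.linspace(1e-3, 0.3, 40)
        ratios = []
        for kap in kappas:
            omega = (kap / stiff_spec.length) ** 2 * stiff_spec.wave_speed_factor()
            mc = bc.modal_coefficients(s, omega, 0.0, stiff_spec)
            ratios.append(bc.tip_shear_amplitude(mc, stiff_spec) / static)
        ratios = np.asarray(ratios)
        assert abs(ratios[0] - 1.0) < 1e-6
        assert np.all(np.diff(np.abs(ratios - 1.0)) > -1e-12)

    def test_matches_modal_third_derivative(self, stiff_spec):
        """Closed form equals -EI * y'''(L) from the mode shape."""
        mc = bc.modal_coefficients(1e-6, 2 * math.pi * 500.0, 0.0, stiff_spec)
        via_mode = -stiff_spec.flexural_rigidity * bc.mode_shape(
            mc, stiff_spec.length, 3
        )
        assert bc.tip_shear_amplitude(mc, stiff_spec) == pytest.approx(
            via_mode, rel=1e-10
        )


class TestResonanceRoots:
    def test_first_roots(self):
        roots = bc.resonance_wavenumbers(2)
        assert roots[0] == pytest.approx(3.9266, abs=1e-4)
        assert roots[1] == pytest.approx(7.0686, abs=1e-4)

    def test_roots_are_zeros_with_sign_change(self):
        roots = bc.resonance_wavenumbers(3)
        for r in roots:
            scale = max(abs(bc.determinant(r - 0.1)), abs(bc.determinant(r + 0.1)))
            assert abs(bc.determinant(r)) < 1e-8 * scale
            assert bc.determinant(r - 1e-3) * bc.determinant(r + 1e-3) < 0

    def test_no_roots_below_first(self):
        kap = np.linspace(1e-6, 3.9, 2000)
        assert np.all(bc.determinant(kap) > 0)

    def test_invalid_count(self):
        with pytest.raises(ParameterError):
            bc.resonance_wavenumbers(0)
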