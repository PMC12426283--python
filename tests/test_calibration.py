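"""Bilinear probe model: forward map, three-standard solve, and inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oecp import (
    CalibrationCoefficients,
    CalibrationStandards,
    ComplexPermittivity,
    FrequencyGrid,
    MaterialModel,
    forward_reflection,
    invert_reflection,
    read_touchstone_s1p,
    solve_three_standard,
    standards_from_touchstone,
)
from oecp.calibration import read_coefficients_csv, write_coefficients_csv
from oecp.errors import (
    ConfigurationError,
    DegenerateStandardsError,
    PhysicalityWarning,
    SingularityError,
)

F0 = 300e6
COEFFS = CalibrationCoefficients.single(F0, 2, -1, 0.5)


def _eps(value: complex) -> ComplexPermittivity:
    return ComplexPermittivity.from_complex(value, F0)


class TestForwardReflection:
    def test_open_standard_form(self):
        # eps* = 1 gives (A2 + A3)/(A1 + 1) = -0.5/3
        assert forward_reflection(COEFFS, _eps(1 + 0j)) == pytest.approx(-1 / 6)

    def test_hand_computed_complex_division(self):
        rho = forward_reflection(COEFFS, _eps(10 - 5j))
        assert rho == pytest.approx(0.35798816568 - 0.05917159763j, abs=1e-10)

    def test_short_circuit_limit_tends_to_a3(self):
        rho = forward_reflection(COEFFS, _eps(1e9 + 0j))
        assert rho == pytest.approx(0.5, abs=1e-8)

    def test_pole_raises(self):
        with pytest.raises(SingularityError):
            forward_reflection(COEFFS, _eps(-2 + 0j))


class TestInvertReflection:
    def test_inverse_of_forward_example(self):
        p = invert_reflection(COEFFS, 0.35798816568047337 - 0.059171597633136085j, F0)
        assert p.eps_complex == pytest.approx(10 - 5j, abs=1e-10)
        assert p.eps_real == pytest.approx(10.0)

    def test_open_reflection_maps_to_unity(self):
        p = invert_reflection(COEFFS, -1 / 6, F0)
        assert p.eps_complex == pytest.approx(1 + 0j, abs=1e-12)

    def test_short_circuit_reflection_raises(self):
        with pytest.raises(SingularityError):
            invert_reflection(COEFFS, 0.5 + 0j, F0)

    def test_implausible_result_flags_but_does_not_raise(self):
        # rho just off A3 inverts to a huge eps'
        with pytest.warns(PhysicalityWarning):
            p = invert_reflection(COEFFS, 0.5 + 1e-6j, F0)
        assert not p.plausible

    def test_full_grid_round_trip_identity(self):
        grid = FrequencyGrid.default()
        rng = np.random.default_rng(7)
        n = len(grid)
        coeffs = CalibrationCoefficients(
            grid.frequencies,
            tuple(2 + rng.standard_normal(n) + 1j * rng.standard_normal(n)),
            tuple(-1 + rng.standard_normal(n) + 1j * rng.standard_normal(n)),
            tuple(0.5 + 0.1 * rng.standard_normal(n) + 0.1j * rng.standard_normal(n)),
        )
        for f in grid:
            eps = ComplexPermittivity.from_complex(40 - 8j, f)
            back = invert_reflection(coeffs, forward_reflection(coeffs, eps), f)
            assert back.eps_complex == pytest.approx(40 - 8j, rel=1e-10)


class TestSolveThreeStandard:
    @staticmethod
    def _standards_from(a1, a2, a3, eps_std_material, noise=0.0, seed=0):
        grid = FrequencyGrid.default()
        rng = np.random.default_rng(seed)
        rho1, rho2, rho3 = [], [], []
        for f in grid:
            eps_std = ComplexPermittivity.from_complex(
                complex(eps_std_material), f
            ).eps_complex
            rho1.append(a3)
            rho2.append((a2 + a3) / (a1 + 1))
            rho3.append((a2 + a3 * eps_std) / (a1 + eps_std))
        if noise:
            rho1 = [r + noise * (rng.standard_normal() + 1j * rng.standard_normal()) for r in rho1]
        mat = MaterialModel("std", eps_std_material.real, 1.0, 0.0)
        return grid, rho1, rho2, rho3, mat

    def test_recovers_hand_built_triple(self):
        # standards generated by the forward map from (2, -1, 0.5), eps_std = 10
        mat = MaterialModel("std10", 10.0, 10.0, 0.0)
        standards = CalibrationStandards(
            (F0,), (0.5,), (-1 / 6,), ((-1 + 0.5 * 10) / (2 + 10),), mat
        )
        coeffs = solve_three_standard(standards, F0)
        assert coeffs.a1[0] == pytest.approx(2, abs=1e-12)
        assert coeffs.a2[0] == pytest.approx(-1, abs=1e-12)
        assert coeffs.a3[0] == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_open_equals_liquid(self):
        mat = MaterialModel("std10", 10.0, 10.0, 0.0)
        standards = CalibrationStandards((F0,), (0.5,), (0.3,), (0.3,), mat)
        with pytest.raises(DegenerateStandardsError):
            solve_three_standard(standards, F0)

    def test_air_like_standard_underdetermined(self):
        mat = MaterialModel("air", 1.0, 1.0, 0.0)
        standards = CalibrationStandards((F0,), (0.5,), (0.2,), (0.3,), mat)
        with pytest.raises(DegenerateStandardsError):
            solve_three_standard(standards, F0)

    @settings(derandomize=True, max_examples=100)
    @given(
        a1r=st.floats(-2, 2), a1i=st.floats(-2, 2),
        a2r=st.floats(-2, 2), a2i=st.floats(-2, 2),
        a3r=st.floats(-2, 2), a3i=st.floats(-2, 2),
        eps_r=st.floats(5, 80), eps_i=st.floats(-20, 0),
    )
    def test_forward_generate_then_solve_round_trip(
        self, a1r, a1i, a2r, a2i, a3r, a3i, eps_r, eps_i
    ):
        a1, a2, a3 = complex(a1r, a1i), complex(a2r, a2i), complex(a3r, a3i)
        eps_std = complex(eps_r, eps_i)
        rho2_den = a1 + 1
        rho3_den = a1 + eps_std
        if abs(rho2_den) < 1e-3 or abs(rho3_den) < 1e-3:
            return  # forward map undefined at its pole
        rho1, rho2 = a3, (a2 + a3) / rho2_den
        rho3 = (a2 + a3 * eps_std) / rho3_den
        if abs(rho2 - rho3) < 1e-6:
            return
        # inject a dispersion-free material whose eps* equals the one used above
        coeffs = solve_three_standard(
            CalibrationStandards(
                (F0,), (rho1,), (rho2,), (rho3,),
                _material_for(eps_std, F0), magnitude_tolerance=1e9,
            ),
            F0,
        )
        for got, want in zip((coeffs.a1[0], coeffs.a2[0], coeffs.a3[0]), (a1, a2, a3)):
            assert got == pytest.approx(want, rel=1e-8, abs=1e-8)

    def test_bilinear_consistency_reproduces_standards(self, library, grid):
        from oecp import G1, ideal_probe_coefficients, synthesize_standards

        true = ideal_probe_coefficients(G1, grid)
        standards = synthesize_standards(true, library["deionized_water"], grid)
        coeffs = solve_three_standard(standards)
        for f in grid:
            rho1, rho2, rho3 = standards.at(f)
            eps_open = ComplexPermittivity.from_complex(1 + 0j, f)
            assert forward_reflection(coeffs, eps_open) == pytest.approx(rho2, abs=1e-10)
            a1, a2, a3 = coeffs.at(f)
            assert a3 == pytest.approx(rho1, abs=1e-12)

    @pytest.mark.parametrize("noise", [1e-4, 1e-3, 1e-2])
    def test_recovery_error_grows_continuously_with_noise(self, library, grid, noise):
        from oecp import G1, ideal_probe_coefficients, invert_reflection, synthesize_standards

        true = ideal_probe_coefficients(G1, grid)
        eps_true = 40.0
        errors = []
        for seed in range(20):
            standards = synthesize_standards(
                true, library["deionized_water"], grid, noise_rho=noise, seed=seed
            )
            coeffs = solve_three_standard(standards)
            f = 300e6
            rho = forward_reflection(true, ComplexPermittivity.from_complex(eps_true, f))
            got = invert_reflection(coeffs, rho, f).eps_real
            errors.append(abs(got - eps_true))
        mean_err = np.mean(errors)
        assert mean_err > 0
        # error scale roughly proportional to the noise scale
        assert mean_err < 500 * noise * 40


def _material_for(eps_std: complex, f: float) -> MaterialModel:
    """Dispersion-free material whose eps* at f equals the given complex value."""
    from oecp.dielectric import EPS0

    sigma = -eps_std.imag * 2 * np.pi * f * EPS0
    return MaterialModel("exact", max(eps_std.real, 1.0), max(eps_std.real, 1.0), 0.0, sigma)


class TestTouchstoneAndCsv:
    def test_ri_ma_db_dialects_agree(self, tmp_path):
        rho = 0.6 * np.exp(1j * np.deg2rad(-40.0))
        ri = tmp_path / "a.s1p"
        ma = tmp_path / "b.s1p"
        db = tmp_path / "c.s1p"
        ri.write_text("! comment\n# MHz S RI R 50\n300 %.10f %.10f\n" % (rho.real, rho.imag))
        ma.write_text("# MHz S MA R 50\n300 0.6 -40\n")
        db.write_text("# GHz S DB R 50\n0.3 %.10f -40\n" % (20 * np.log10(0.6)))
        for path in (ri, ma, db):
            freqs, s11 = read_touchstone_s1p(path)
            assert freqs[0] == pytest.approx(300e6)
            assert s11[0] == pytest.approx(rho, abs=1e-9)

    def test_standards_from_touchstone_and_solve(self, tmp_path, library):
        # write a consistent triple for coefficients (2, -1, 0.5) and water at 300 MHz
        from oecp import evaluate_debye

        f = 300e6
        eps_std = evaluate_debye(library["deionized_water"], f).eps_complex
        rho1, rho2 = 0.5 + 0j, -1 / 6 + 0j
        rho3 = (-1 + 0.5 * eps_std) / (2 + eps_std)
        paths = []
        for name, rho in (("short", rho1), ("open", rho2), ("liquid", rho3)):
            p = tmp_path / f"{name}.s1p"
            p.write_text("# Hz S RI R 50\n%.1f %.12f %.12f\n" % (f, rho.real, rho.imag))
            paths.append(p)
        standards = standards_from_touchstone(*paths, library["deionized_water"])
        coeffs = solve_three_standard(standards)
        assert coeffs.a1[0] == pytest.approx(2, abs=1e-6)
        assert coeffs.a2[0] == pytest.approx(-1, abs=1e-6)

    def test_coefficients_csv_round_trip(self, tmp_path, grid):
        from oecp import G1, ideal_probe_coefficients

        coeffs = ideal_probe_coefficients(G1, grid)
        path = tmp_path / "coeffs.csv"
        write_coefficients_csv(coeffs, path)
        again = read_coefficients_csv(path)
        assert np.allclose(again.a1, coeffs.a1, rtol=1e-9)
        assert np.allclose(again.a3, coeffs.a3, rtol=1e-9)

    def test_passivity_bound_enforced(self):
        mat = MaterialModel("std10", 10.0, 10.0, 0.0)
        with pytest.raises(ConfigurationError):
            CalibrationStandards((F0,), (1.5,), (0.2,), (0.3,), mat)
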