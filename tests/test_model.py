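"""Model core: linear operator, energies, coupling forces, gradient flow."""

import numpy as np
import pytest

import mapcrystal as mc
from mapcrystal.grid import KC_Z
from mapcrystal.model import (apply_linear, coupling_energy, coupling_force,
                              linear_spectrum, pack, rhs, rhs_stacked,
                              single_field_energy, total_energy, unpack)

ALL_KINDS = ["product2", "product4", "gradient2", "gradient4"]


# ---------------------------------------------------------------------------
# linear operator
# ---------------------------------------------------------------------------

class TestLinearSpectrum:
    def test_maximum_at_critical_circle(self):
        k = np.linspace(0, 4 * KC_Z, 4001)
        lam = linear_spectrum(k**2, r=0.3, kc=KC_Z)
        assert lam.max() == pytest.approx(0.3, abs=1e-12)
        assert k[np.argmax(lam)] == pytest.approx(KC_Z, rel=1e-3)

    def test_dc_value_is_r_minus_one(self):
        assert linear_spectrum(0.0, r=0.05, kc=KC_Z) == pytest.approx(-0.95)

    def test_invalid_kc_rejected(self):
        with pytest.raises(ValueError):
            linear_spectrum(1.0, r=0.1, kc=0.0)

    def test_seeded_mode_grows_at_linear_rate(self, small_grid):
        """A single Fourier mode integrated in the linear regime grows as
        exp(λ(k) t), measured from the log-amplitude slope."""
        from mapcrystal.integrate import cn_step
        from mapcrystal.model import pack
        model = mc.ModelSpec(r_z=0.05, grid=small_grid)
        kvec = small_grid.mode_wavevector(4, 1)
        z0 = mc.stripes(small_grid, k=kvec, amplitude=1e-4)
        lam = linear_spectrum(kvec[0] ** 2 + kvec[1] ** 2, 0.05, KC_Z)
        cfg = mc.IntegratorConfig(t_end=1.0, newton_tol=1e-13,
                                  gmres_tol=1e-10)
        dt = 0.05
        u = pack(mc.FieldState(0.0, z0))
        amps = [np.abs(u[0] + 1j * u[1]).max()]
        for _ in range(100):
            u, _ = cn_step(u, dt, model, cfg)
            amps.append(np.abs(u[0] + 1j * u[1]).max())
        t = dt * np.arange(len(amps))
        slope = np.polyfit(t, np.log(amps), 1)[0]
        # amplitude ≪ 1 keeps the cubic term negligible; dt small enough
        # that the CN phase-slope bias λ³dt²/12 is below the tolerance
        assert slope == pytest.approx(lam, rel=1e-6)


class TestApplyLinear:
    def test_plane_wave_at_kc_scaled_by_r(self, small_grid):
        z = mc.stripes(small_grid, orientation=0.0, amplitude=1.0)
        out = apply_linear(z, 0.3, KC_Z, small_grid)
        assert np.allclose(out, 0.3 * z, atol=1e-12)

    def test_constant_field_scaled_by_r_minus_one(self, small_grid):
        f = np.full(small_grid.shape, 2.0)
        out = apply_linear(f, 0.3, KC_Z, small_grid)
        assert np.allclose(out, (0.3 - 1.0) * f)
        assert np.isrealobj(out)

    def test_shape_mismatch_rejected(self, small_grid):
        with pytest.raises(ValueError):
            apply_linear(np.zeros((8, 8)), 0.3, KC_Z, small_grid)

    def test_matches_finite_difference_discretization(self):
        """Spectral L̂ agrees with r − (k_c² + Δ_h)²/k_c⁴ built from the
        5-point Laplacian to O(h²)."""
        errs = []
        for n in (64, 128):
            g = mc.GridSpec(n, n, 4, 4)
            f = mc.bandpass_gwn(g, target_power=1.0, seed=3,
                                complex_valued=False)
            spec = apply_linear(f, 0.2, KC_Z, g)

            def lap(u, h):
                return (np.roll(u, 1, 0) + np.roll(u, -1, 0)
                        + np.roll(u, 1, 1) + np.roll(u, -1, 1) - 4 * u) / h**2

            h = g.dx
            lf = lap(f, h)
            fd = 0.2 * f - (KC_Z**2 * f + lf + (lap(lf, h)
                            + 2 * KC_Z**2 * lf) / KC_Z**4 * KC_Z**4
                            / KC_Z**4 * 0) - 0  # assembled below
            # assemble (kc² + Δ)² f = kc⁴ f + 2 kc² Δf + Δ²f explicitly
            fd = 0.2 * f - (KC_Z**4 * f + 2 * KC_Z**2 * lf + lap(lf, h)) / KC_Z**4
            errs.append(np.max(np.abs(spec - fd)))
        # halving h divides the discretization error by ~4
        assert errs[0] / errs[1] > 3.0


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

class TestSingleFieldEnergy:
    def test_zero_state_zero_energy(self, small_grid):
        m = mc.ModelSpec(r_z=0.05, fields=(mc.RealFieldSpec(r=0.25),),
                         grid=small_grid)
        st = mc.FieldState(0.0, np.zeros(small_grid.shape, complex),
                           (np.zeros(small_grid.shape),))
        assert single_field_energy(st, m) == 0.0

    def test_stripe_energy_closed_form(self, small_grid):
        """The uncoupled OP stripe z = √r e^{i k_c x} has energy density
        −r²/2."""
        r = 0.05
        m = mc.ModelSpec(r_z=r, grid=small_grid)
        z = mc.stripes(small_grid, orientation=0.0, amplitude=np.sqrt(r))
        st = mc.FieldState(0.0, z)
        assert single_field_energy(st, m) == pytest.approx(-r**2 / 2, rel=1e-12)


class TestCouplingEnergy:
    def test_perpendicular_stripes_zero_gradient_energy(self, small_grid):
        x, y = small_grid.coords()
        z = np.exp(1j * KC_Z * x)
        o = np.cos(KC_Z * y)
        st = mc.FieldState(0.0, z, (o,))
        for kind in ("gradient2", "gradient4"):
            e = coupling_energy(st, [mc.CouplingSpec(kind, 5.0)], small_grid)
            assert e == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_zero_strength_zero_energy(self, kind, coupled_state, small_grid):
        e = coupling_energy(coupled_state, [mc.CouplingSpec(kind, 0.0)],
                            small_grid)
        assert e == 0.0

    def test_parallel_stripes_match_quadrature(self, small_grid):
        """gradient4 energy of parallel stripes against brute-force
        quadrature of ε|∇z·∇o|⁴ from the analytic gradients."""
        A, B, phi, eps = 0.21, 0.43, 0.7, 3.0
        k = KC_Z
        x, y = small_grid.coords()
        z = A * np.exp(1j * k * x)
        o = B * np.cos(k * x + phi)
        st = mc.FieldState(0.0, z, (o,))
        e = coupling_energy(st, [mc.CouplingSpec("gradient4", eps)],
                            small_grid)
        xs = (np.arange(1024) + 0.5) / 1024 * small_grid.lx
        s = (1j * k * A * np.exp(1j * k * xs)) * (-k * B * np.sin(k * xs + phi))
        oracle = eps * np.mean(np.abs(s) ** 4)
        assert e == pytest.approx(oracle, rel=1e-10)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            mc.CouplingSpec("banana", 1.0)


# ---------------------------------------------------------------------------
# forces: FD-gradient contract
# ---------------------------------------------------------------------------

def _fd_force(state, cps, grid, field, idx, h):
    """Central finite difference of N·coupling_energy at one grid point."""
    n = grid.nx * grid.ny
    j, i = idx

    def energy_with(val):
        st = state.copy()
        if field == "re":
            st.z[j, i] = st.z[j, i] + val
        elif field == "im":
            st.z[j, i] = st.z[j, i] + 1j * val
        else:
            st.os[field][j, i] += val
        return coupling_energy(st, cps, grid)

    return -(energy_with(h) - energy_with(-h)) / (2 * h) * n


class TestCouplingForce:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_force_is_negative_energy_gradient(self, kind, coupled_state,
                                               small_grid):
        """coupling_force equals the FD gradient of coupling_energy, with the
        error scaling as h² (the defining self-consistency contract)."""
        cps = [mc.CouplingSpec(kind, 2.0)]
        fz, fos = coupling_force(coupled_state, cps, small_grid)
        idx = (5, 7)
        scale = max(1.0, abs(fos[0][idx]), abs(fz[idx]))
        errs = {}
        for h in (1e-3, 5e-4):
            e_re = abs(_fd_force(coupled_state, cps, small_grid, "re", idx, h)
                       - 2 * fz[idx].real)
            e_im = abs(_fd_force(coupled_state, cps, small_grid, "im", idx, h)
                       - 2 * fz[idx].imag)
            e_o = abs(_fd_force(coupled_state, cps, small_grid, 0, idx, h)
                      - fos[0][idx])
            errs[h] = max(e_re, e_im, e_o) / scale
        assert errs[5e-4] < 1e-4
        # O(h²): halving h shrinks the FD error by ≈ 4, unless both sit on
        # the round-off floor (quadratic energies differentiate exactly)
        assert errs[5e-4] < max(errs[1e-3], 1e-9)

    def test_zero_strength_zero_force(self, coupled_state, small_grid):
        fz, fos = coupling_force(coupled_state,
                                 [mc.CouplingSpec("gradient4", 0.0)],
                                 small_grid)
        assert not np.any(fz) and not np.any(fos[0])

    def test_perpendicular_stripes_zero_force(self, small_grid):
        x, y = small_grid.coords()
        st = mc.FieldState(0.0, np.exp(1j * KC_Z * x), (np.cos(KC_Z * y),))
        for kind in ("gradient2", "gradient4"):
            fz, fos = coupling_force(st, [mc.CouplingSpec(kind, 7.0)],
                                     small_grid)
            assert np.max(np.abs(fz)) < 1e-12
            assert np.max(np.abs(fos[0])) < 1e-12

    def test_real_real_pair_consistency(self, small_grid):
        o1 = mc.bandpass_gwn(small_grid, target_power=0.2, seed=4,
                             complex_valued=False)
        o2 = mc.bandpass_gwn(small_grid, target_power=0.3, seed=5,
                             complex_valued=False)
        st = mc.FieldState(0.0, np.zeros(small_grid.shape, complex), (o1, o2))
        cps = [mc.CouplingSpec("gradient4", 1.5, pair=(1, 2))]
        _, fos = coupling_force(st, cps, small_grid)
        idx = (3, 11)
        for fi in (0, 1):
            fd = _fd_force(st, cps, small_grid, fi, idx, 5e-4)
            assert fd == pytest.approx(fos[fi][idx], rel=1e-4, abs=1e-8)


# ---------------------------------------------------------------------------
# rhs
# ---------------------------------------------------------------------------

class TestRhs:
    def test_uncoupled_stripe_is_fixed_point(self, small_grid):
        m = mc.ModelSpec(r_z=0.05, grid=small_grid)
        z = mc.stripes(small_grid, orientation=0.0, amplitude=np.sqrt(0.05))
        d = rhs(mc.FieldState(0.0, z), m)
        assert np.max(np.abs(d.z)) < 1e-12

    def test_bias_drives_empty_state(self, small_grid):
        m = mc.ModelSpec(r_z=0.05,
                         fields=(mc.RealFieldSpec(r=0.25, gamma=0.15, c=2.0),),
                         grid=small_grid)
        st = mc.FieldState(0.0, np.zeros(small_grid.shape, complex),
                           (np.zeros(small_grid.shape),))
        d = rhs(st, m)
        assert np.allclose(d.os[0], 0.15 / 2.0)
        assert not np.any(d.z)

    def test_rhs_is_negative_total_energy_gradient(self, coupled_state,
                                                   small_grid):
        """Gradient-flow consistency: the rhs equals −δE/δu field-by-field
        (FD oracle on the total energy, γ term included), up to the c_i
        factors."""
        m = mc.ModelSpec(
            r_z=0.05,
            fields=(mc.RealFieldSpec(r=0.25, gamma=0.2, c=3.0),),
            couplings=(mc.CouplingSpec("gradient4", 2.0),
                       mc.CouplingSpec("product2", 0.3)),
            grid=small_grid)
        st = coupled_state
        d = rhs(st, m)
        n = small_grid.nx * small_grid.ny
        h = 5e-4
        idx = (9, 2)
        j, i = idx

        def e_of(dz, do):
            s2 = st.copy()
            s2.z[j, i] += dz
            s2.os[0][j, i] += do
            return total_energy(s2, m)

        fd_re = -(e_of(h, 0) - e_of(-h, 0)) / (2 * h) * n
        fd_im = -(e_of(1j * h, 0) - e_of(-1j * h, 0)) / (2 * h) * n
        fd_o = -(e_of(0, h) - e_of(0, -h)) / (2 * h) * n
        assert fd_re == pytest.approx(2 * d.z[idx].real, rel=2e-4, abs=1e-8)
        assert fd_im == pytest.approx(2 * d.z[idx].imag, rel=2e-4, abs=1e-8)
        assert fd_o == pytest.approx(3.0 * d.os[0][idx], rel=2e-4, abs=1e-8)

    def test_energy_descent_along_rhs(self, coupled_state, small_grid):
        """⟨δE/δu, ∂t u⟩ ≤ 0 on a random state (numerical inner product)."""
        m = mc.ModelSpec(r_z=0.05,
                         fields=(mc.RealFieldSpec(r=0.25, gamma=0.2, c=2.0),),
                         couplings=(mc.CouplingSpec("gradient4", 0.01),),
                         grid=small_grid)
        st = coupled_state
        d = rhs(st, m)
        eps = 1e-9
        st2 = st.copy()
        st2.z = st.z + eps * d.z
        st2.os = (st.os[0] + eps * d.os[0],)
        de = total_energy(st2, m) - total_energy(st, m)
        assert de < 0
        # and the decrement matches −⟨2|ż|² + c ȯ²⟩ to first order
        pred = -eps * float(np.mean(2 * np.abs(d.z) ** 2
                                    + 2.0 * d.os[0] ** 2))
        assert de == pytest.approx(pred, rel=1e-3)

    def test_translation_equivariance(self, coupled_state, small_grid):
        m = mc.ModelSpec(r_z=0.05,
                         fields=(mc.RealFieldSpec(r=0.25, gamma=0.2),),
                         couplings=(mc.CouplingSpec("gradient4", 2.0),),
                         grid=small_grid)
        d = rhs(coupled_state, m)
        shifted = mc.FieldState(0.0, np.roll(coupled_state.z, 5, axis=1),
                                (np.roll(coupled_state.os[0], 5, axis=1),))
        ds = rhs(shifted, m)
        assert np.allclose(ds.z, np.roll(d.z, 5, axis=1), atol=1e-12)
        assert np.allclose(ds.os[0], np.roll(d.os[0], 5, axis=1), atol=1e-12)

    def test_real_fields_stay_real(self, coupled_state, small_grid):
        m = mc.ModelSpec(r_z=0.05,
                         fields=(mc.RealFieldSpec(r=0.25, gamma=0.2),),
                         couplings=(mc.CouplingSpec("gradient2", 1.0),),
                         grid=small_grid)
        u = pack(coupled_state)
        du = rhs_stacked(u, m)
        assert du.dtype.kind == "f"
        st = unpack(u)
        assert np.isrealobj(st.os[0])


class TestSpecValidation:
    def test_noninteger_wavelength_rejected(self):
        g = mc.GridSpec(64, 64, 8, 8)
        with pytest.raises(ValueError):
            mc.ModelSpec(r_z=0.05, fields=(mc.RealFieldSpec(r=0.25, w=0.77),),
                         grid=g)

    def test_detuned_integer_ratio_accepted(self):
        g = mc.GridSpec(128, 128, 8, 8)
        m = mc.ModelSpec(r_z=0.05,
                         fields=(mc.RealFieldSpec(r=0.25, w=0.75),),
                         grid=g)
        assert m.fields[0].kc == pytest.approx(0.75 * KC_Z)

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError):
            mc.CouplingSpec("gradient4", -1.0)

    def test_coarse_mesh_rejected(self):
        with pytest.raises(ValueError):
            mc.GridSpec(32, 32, 8, 8)
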