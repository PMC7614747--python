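import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

import neodose as nd
from neodose.sar import (ExposureField, PowerBudget, _mean_b1_slice,
                         mass_averaged_sar_10g, normalize, pointwise_sar,
                         region_average_sar)
from neodose.tissue_db import TissueTable

from conftest import brute_force_ps10, toy_model


def _uniform_field(model, E=100.0, B1=1.0, absorbed=None):
    shape = model.labels.shape
    absorbed = absorbed if absorbed is not None else 0.6
    budget = PowerBudget(1.0, 0.1, 0.9 - absorbed, absorbed)
    return ExposureField(np.full(shape, float(E)),
                         np.full(shape, complex(B1)),
                         budget, model.labels.shape[2] // 2
                         if model.reference_slice is None else model.reference_slice)


def _table_for(model, sigma=0.5, rho=1000.0):
    rows = []
    for lab, name in model.tissue_names.items():
        rows.append({"tissue": name, "freq_MHz": 297.0, "eps_r": 50.0,
                     "sigma_S_per_m": sigma, "rho_kg_m3": rho, "k_W_mK": 0.5,
                     "c_J_kgK": 3500.0, "perfusion_ml_min_kg": 0.0,
                     "qmet_W_kg": 0.0, "source": "test"})
    return TissueTable(pd.DataFrame(rows))


class TestPointwise:
    def test_formula(self):
        m = toy_model(np.ones((4, 4, 4), dtype=np.int16))
        table = _table_for(m, sigma=0.5, rho=1000.0)
        sar = pointwise_sar(_uniform_field(m, E=100.0), m, table)
        assert sar[m.masks["whole_body"]] == pytest.approx(5.0)

    def test_zero_field_gives_zero_sar(self, sphere_model, adult_table):
        sar = pointwise_sar(_uniform_field(sphere_model, E=0.0),
                            sphere_model, adult_table)
        assert not sar.any()

    def test_air_and_blanket_carry_no_sar(self, sphere_model, adult_table):
        ins = nd.add_blanket(sphere_model, 4.0, face_aperture=None)
        sar = pointwise_sar(_uniform_field(ins), ins, adult_table)
        assert not sar[ins.masks["blanket"]].any()
        assert not sar[ins.labels == 0].any()

    def test_zero_density_tissue_rejected(self):
        m = toy_model(np.ones((3, 3, 3), dtype=np.int16))
        table = _table_for(m, rho=0.0)
        with pytest.raises(ValueError, match="density"):
            pointwise_sar(_uniform_field(m), m, table)

    def test_absorbed_power_closure_on_constructed_deposition(self, sphere_model,
                                                              adult_table):
        # field scaled by the constructor to deposit exactly 59% of 1 W
        f = nd.surrogate_field(sphere_model, adult_table, kind="radial_gradient")
        sar = pointwise_sar(f, sphere_model, adult_table)
        rho = sphere_model.density_grid()
        total = (sar * rho).sum() * sphere_model.voxel_volume_m3
        assert total == pytest.approx(f.budget.absorbed_W, rel=0.01)


class TestRegionAverage:
    def test_uniform(self, sphere_model):
        sar = np.where(sphere_model.masks["whole_body"], 2.0, 0.0)
        assert region_average_sar(sar, sphere_model,
                                  sphere_model.masks["whole_body"]) == pytest.approx(2.0)

    def test_two_equal_mass_halves(self):
        m = toy_model(np.ones((4, 4, 4), dtype=np.int16))
        sar = np.ones((4, 4, 4))
        sar[2:] = 3.0
        assert region_average_sar(sar, m, m.masks["whole_body"]) == pytest.approx(2.0)

    def test_against_direct_summation(self, sphere_model):
        rng = np.random.default_rng(11)
        sar = rng.random(sphere_model.labels.shape)
        mask = sphere_model.masks["whole_body"]
        rho = sphere_model.density_grid()
        expected = float((sar * rho)[mask].sum() / rho[mask].sum())
        got = region_average_sar(sar, sphere_model, mask)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_mask_rejected(self, sphere_model):
        with pytest.raises(ValueError, match="empty"):
            region_average_sar(np.zeros(sphere_model.labels.shape), sphere_model,
                               np.zeros(sphere_model.labels.shape, dtype=bool))


def _random_toy(rng):
    # voxels large enough (5-9 mm) that 10 g cubes span 2-5 voxels
    shape = tuple(rng.integers(8, 17, 3))
    labels = (rng.random(shape) < 0.8).astype(np.int16)
    vox = float(rng.uniform(5.0, 9.0))
    rho = float(rng.uniform(700, 1800))
    m = toy_model(labels, voxel_size_mm=vox, densities={1: rho})
    sar = rng.random(shape) * labels
    return m, sar


class TestPsSAR10g:
    def test_uniform_sar_uniform_density(self):
        m = toy_model(np.ones((14, 14, 14), dtype=np.int16))
        sar = np.full((14, 14, 14), 2.0)
        ps, loc, grid, valid = mass_averaged_sar_10g(sar, m)
        assert ps == pytest.approx(2.0)
        assert valid.any()

    def test_insufficient_mass_rejected(self):
        m = toy_model(np.ones((2, 2, 1), dtype=np.int16), voxel_size_mm=1.0)
        with pytest.raises(ValueError, match="mass"):
            mass_averaged_sar_10g(np.ones((2, 2, 1)), m)

    def test_matches_exhaustive_brute_force(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            m, sar = _random_toy(rng)
            rho = m.density_grid()
            mass = rho * m.voxel_volume_m3
            if mass.sum() < 0.010:
                continue
            ps, loc, grid, valid = mass_averaged_sar_10g(sar, m)
            ref, ref_loc, ref_valid = brute_force_ps10(sar, mass, 0.010)
            assert ps == pytest.approx(ref, rel=1e-9)
            assert loc == ref_loc
            assert np.array_equal(valid, ref_valid)

    def test_peak_decreases_with_target_mass(self):
        rng = np.random.default_rng(5)
        m, sar = _random_toy(rng)
        masses = [0.001, 0.010, 0.030]
        peaks = []
        for t in masses:
            try:
                ps, *_ = mass_averaged_sar_10g(sar, m, target_mass_kg=t)
            except ValueError:
                continue
            peaks.append(ps)
        assert all(a >= b - 1e-12 for a, b in zip(peaks, peaks[1:]))

    def test_tie_broken_by_lowest_linear_index(self):
        # two exactly equal, well-separated peaks: every cube capturing
        # the first peak ties with its mirror at the second; the lowest
        # linear index must win
        m = toy_model(np.ones((16, 16, 16), dtype=np.int16), voxel_size_mm=4.0)
        sar = np.zeros((16, 16, 16))
        sar[3, 3, 3] = sar[12, 12, 12] = 100.0
        ps, loc, grid, valid = mass_averaged_sar_10g(sar, m)
        assert loc == (3, 3, 3)
        assert grid[3, 3, 3] == grid[12, 12, 12]

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_oracle_equivalence_property(self, seed):
        """Cube growth equals exhaustive search on arbitrary random grids."""
        rng = np.random.default_rng(seed)
        m, sar = _random_toy(rng)
        mass = m.density_grid() * m.voxel_volume_m3
        if mass.sum() < 0.010:
            return
        ref, ref_loc, _ = brute_force_ps10(sar, mass, 0.010)
        if ref_loc is None:
            return
        ps, loc, *_ = mass_averaged_sar_10g(sar, m)
        assert ps == pytest.approx(ref, rel=1e-9)
        assert loc == ref_loc

    def test_ordering_invariant_on_phantom(self, neonate_model, scaled_table):
        f = nd.surrogate_field(neonate_model, scaled_table, kind="radial_gradient")
        res = nd.compute_sar(f, neonate_model, scaled_table)
        assert res.head_avg <= res.psSAR10g <= res.sar.max() + 1e-12
        assert res.whole_body_avg <= res.psSAR10g


class TestNormalize:
    def test_drive_invariance(self, sphere_model, adult_table):
        f1 = nd.surrogate_field(sphere_model, adult_table, kind="radial_gradient")
        f2 = f1.scaled(2.0)
        r1 = nd.compute_sar(f1, sphere_model, adult_table)
        r2 = nd.compute_sar(f2, sphere_model, adult_table)
        for mode in ("input_power", "net_forward", "absorbed", "b1_slice"):
            for region, v in r1.normalizations[mode].items():
                assert r2.normalizations[mode][region] == pytest.approx(v, rel=1e-9)
        # un-normalized values do scale with drive power
        assert r2.head_avg == pytest.approx(2.0 * r1.head_avg, rel=1e-9)

    def test_denominators(self, sphere_model, adult_table):
        f = nd.surrogate_field(sphere_model, adult_table, kind="uniform")
        res = nd.compute_sar(f, sphere_model, adult_table)
        b = f.budget
        n = res.normalizations
        assert n["net_forward"]["head_avg"] == pytest.approx(
            res.head_avg / (b.forward_W - b.reflected_W))
        assert n["absorbed"]["psSAR10g"] == pytest.approx(
            res.psSAR10g / b.absorbed_W)
        assert n["b1_slice"]["head_avg"] == pytest.approx(
            res.head_avg / res.mean_B1_slice ** 2)

    def test_zero_denominator_rejected(self, sphere_model, adult_table):
        f = _uniform_field(sphere_model)
        f.budget = PowerBudget(1.0, 1.0, 0.0, 0.0)
        res = nd.compute_sar.__wrapped__ if hasattr(nd.compute_sar, "__wrapped__") else None
        sar = pointwise_sar(f, sphere_model, adult_table)
        from neodose.sar import SARResult
        r = SARResult(sar, 1.0, 1.0, 1.0, (0, 0, 0),
                      np.ones_like(sar, dtype=bool), sar, 1.0, f.budget)
        with pytest.raises(ZeroDivisionError):
            normalize(r, "net_forward")


class TestSurrogate:
    def test_uniform_kind_is_constant(self, sphere_model, adult_table):
        f = nd.surrogate_field(sphere_model, adult_table, kind="uniform")
        assert np.ptp(f.E_rms) == pytest.approx(0.0)

    @pytest.mark.parametrize("kind", ["uniform", "radial_gradient",
                                      "superficial_hotspot"])
    def test_budget_closure(self, sphere_model, adult_table, kind):
        f = nd.surrogate_field(sphere_model, adult_table, kind=kind)
        b = f.budget
        assert b.reflected_W + b.radiated_W + b.absorbed_W == pytest.approx(
            b.forward_W, rel=1e-12)

    def test_b1_efficiency_honored(self, sphere_model, adult_table):
        f = nd.surrogate_field(sphere_model, adult_table, kind="radial_gradient",
                               P_in=4.0, b1_efficiency_uT_per_sqrtW=0.53)
        assert _mean_b1_slice(f, sphere_model) == pytest.approx(0.53 * 2.0, rel=1e-9)

    def test_inconsistent_budget_rejected(self, sphere_model, adult_table):
        with pytest.raises(ValueError):
            nd.surrogate_field(sphere_model, adult_table,
                               reflected_fraction=0.6, absorbed_fraction=0.6)

    def test_imported_round_trip(self, tmp_path, sphere_model, adult_table):
        f = nd.surrogate_field(sphere_model, adult_table, kind="superficial_hotspot")
        nd.write_field(f, tmp_path / "f.h5")
        back = nd.read_field(tmp_path / "f.h5")
        assert np.array_equal(back.E_rms, f.E_rms)
        assert np.array_equal(back.B1_plus, f.B1_plus)
        assert back.budget == f.budget
        assert back.central_slice == f.central_slice

    def test_absorbed_power_matches_analytic_integral(self, adult_table):
        # radial-gradient pattern on a homogeneous sphere: compare the
        # voxelized deposition profile with the closed-form volume integral
        R, vox = 0.05, 1.0
        m = nd.generate_phantom(nd.sphere_spec(radius_mm=R * 1e3, voxel_size_mm=vox))
        f = nd.surrogate_field(m, adult_table, kind="radial_gradient",
                               params={"axial_sigma_mm": 100.0})
        sigma = 0.77  # muscle at 297 MHz
        shape = m.labels.shape
        c = shape[0] * vox * 1e-3 / 2
        r_ref = c
        sz = 0.100

        def disk(z):
            a2 = R ** 2 - z ** 2
            return np.exp(-2 * (z / sz) ** 2) * np.pi / 2 * a2 ** 2

        integral, _ = integrate.quad(disk, -R, R)
        I_analytic = integral / r_ref ** 2  # integral of e^2 over the sphere
        # probe |E|^2 at an off-axis voxel and compare the ratio
        # |E|^2 / P_abs with the analytic e^2 / (sigma * I); the probe's
        # pattern value is evaluated at the exact voxel-center coordinates
        z0_idx = m.reference_slice
        i = int((c * 1e3 + 25.0) / vox)
        j = shape[1] // 2
        xc = (i + 0.5) * vox * 1e-3 - c
        yc = (j + 0.5) * vox * 1e-3 - c
        zc = (z0_idx + 0.5) * vox * 1e-3 - z0_idx * vox * 1e-3
        e2 = (np.hypot(xc, yc) / r_ref * np.exp(-(zc / sz) ** 2)) ** 2
        expected_ratio = e2 / (sigma * I_analytic)
        got_ratio = f.E_rms[i, j, z0_idx] ** 2 / f.budget.absorbed_W
        assert got_ratio == pytest.approx(expected_ratio, rel=0.02)


class TestShiftExperiment:
    def test_zero_shift_matches_unshifted(self, sphere_model, adult_table):
        f = nd.surrogate_field(sphere_model, adult_table, kind="radial_gradient")
        res = nd.compute_sar(f, sphere_model, adult_table)
        table = nd.shift_experiment(sphere_model, f, adult_table, [(0, 0, 0)])
        row = table.iloc[0]
        assert row["psSAR10g_per_B1sq"] == pytest.approx(
            res.normalizations["b1_slice"]["psSAR10g"], rel=1e-12)

    def test_uniform_field_invariant_under_shifts(self, adult_table):
        m = nd.generate_phantom(nd.sphere_spec(radius_mm=20.0, voxel_size_mm=2.0,
                                               margin_mm=30.0))
        f = _uniform_field(m)
        table = nd.shift_experiment(m, f, adult_table,
                                    [(0, 0, 0), (10, 0, 0), (0, -10, 10)])
        vals = table["psSAR10g_per_B1sq"]
        assert vals.max() == pytest.approx(vals.min(), rel=1e-9)
        assert not table["flagged"].any()

    def test_gradient_overlap_hand_computed(self, adult_table):
        # 1D |E| gradient along z on a single-tissue slab; shifting the
        # model samples a different window of the fixed field
        m = nd.generate_phantom(nd.slab_spec(nx=6, ny=6, nz=20, tissue="muscle"))
        shape = m.labels.shape
        E = np.zeros(shape)
        E[:] = np.linspace(10.0, 200.0, shape[2])[None, None, :]
        budget = PowerBudget(1.0, 0.2, 0.2, 0.6)
        f = ExposureField(E, np.ones(shape, dtype=complex), budget, shape[2] // 2)
        shifted = nd.shift_model(m, (0, 0, 8.0))  # 4 voxels at 2 mm
        sar = pointwise_sar(f, shifted, adult_table)
        # independent hand computation over the surviving overlap
        mask = shifted.masks["whole_body"]
        rho, sigma = 1090.0, 0.77
        expected = (sigma * E[mask] ** 2 / rho).mean()
        got = region_average_sar(sar, shifted, mask)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_large_clip_flagged(self, adult_table):
        m = nd.generate_phantom(nd.sphere_spec(radius_mm=20.0, voxel_size_mm=2.0))
        f = _uniform_field(m)
        table = nd.shift_experiment(m, f, adult_table, [(30.0, 0, 0)])
        assert table["flagged"].iloc[0]
        assert table["clipped_fraction"].iloc[0] > 0.20
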