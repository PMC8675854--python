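"""Langevin integration and potential landscapes."""

import numpy as np
import pytest

from bgct import (Landscape, ModelParameters, NoiseSpec, estimate_pss,
                  find_equilibria, langevin_simulate, potential)


def test_zero_noise_stays_at_equilibrium(table_params):
    p = table_params.replace(T42=1.0, T53=1.0)
    eq = find_equilibria(p, n_starts=256)[0]
    _t, X = langevin_simulate(p, NoiseSpec(D=0.0, seed=1), eq.state, 200.0)
    assert np.max(np.abs(X - eq.state)) < 1e-6


def test_same_seed_bit_identical(table_params):
    p = table_params.replace(T42=2.0, T53=0.0)
    x0 = np.full(7, 0.5)
    spec = NoiseSpec(D=1e-6, seed=42)
    _t, A = langevin_simulate(p, spec, x0, 300.0)
    _t, B = langevin_simulate(p, spec, x0, 300.0)
    np.testing.assert_array_equal(A, B)
    _t, C = langevin_simulate(p, NoiseSpec(D=1e-6, seed=43), x0, 300.0)
    assert np.any(A != C)


def test_ou_stationary_variance(decoupled_params):
    """With all couplings off each variable is an OU process with
    relaxation time R C, so Var = D * R * C."""
    p = decoupled_params
    D = 1e-4
    _t, X = langevin_simulate(p, NoiseSpec(D=D, seed=7),
                              p.R * p.I, 150_000.0, record_step=2.0,
                              burn_in=200.0)
    var = np.var(X[:, 0])
    expect = D * p.R[0] * p.C[0]
    assert var == pytest.approx(expect, rel=0.05)


def test_noise_spec_validation():
    with pytest.raises(ValueError):
        NoiseSpec(D=-1.0)
    with pytest.raises(ValueError):
        NoiseSpec(dt=0.0)
    with pytest.raises(ValueError):
        NoiseSpec(applied_to=(0, 9))


def test_noise_on_subset_of_equations(table_params):
    p = table_params.replace(T42=1.0, T53=1.0)
    eq = find_equilibria(p, n_starts=256)[0]
    spec = NoiseSpec(D=1e-6, seed=5, applied_to=(1,))
    _t, X = langevin_simulate(p, spec, eq.state, 500.0)
    # driven variable fluctuates far more than a passively coupled one
    assert np.std(X[:, 0]) > 3.0 * np.std(X[:, 3])


def test_uniform_pss_gives_flat_potential():
    k = 25
    pss = np.full((k, k), 1.0 / k ** 2)
    land = potential(Landscape(bin_edges=(np.linspace(0, 1, k + 1),
                                          np.linspace(0, 1, k + 1)),
                               pss=pss, n_samples=10_000))
    occ = land.pss > 0
    np.testing.assert_allclose(land.U[occ], np.log(k ** 2), atol=1e-12)
    assert land.minima == []
    assert not land.ring_detected


def test_two_gaussian_pss_gives_two_minima():
    k = 80
    c = np.linspace(0, 1, k)
    X, Y = np.meshgrid(c, c, indexing="ij")
    blob = lambda x0, y0: np.exp(-(((X - x0) ** 2 + (Y - y0) ** 2)
                                   / (2 * 0.05 ** 2)))
    pss = blob(0.25, 0.25) + blob(0.75, 0.75)
    pss /= pss.sum()
    land = potential(Landscape(bin_edges=(np.linspace(0, 1, k + 1),) * 2,
                               pss=pss, n_samples=1_000_000))
    assert len(land.minima) == 2
    got = sorted(land.minima)
    np.testing.assert_allclose(got, [(0.25, 0.25), (0.75, 0.75)], atol=0.02)
    assert not land.ring_detected


def test_pss_normalization_and_modes(table_params):
    p = table_params.replace(T42=1.0, T53=1.0)
    land = estimate_pss(p, NoiseSpec(D=1e-6, seed=3), ensemble=20,
                        t_end=600.0, burn_in=300.0, grid=40)
    assert land.pss.sum() == pytest.approx(1.0, abs=1e-12)
    end = estimate_pss(p, NoiseSpec(D=1e-6, seed=3), ensemble=20,
                       t_end=600.0, burn_in=300.0, grid=40,
                       sampling="endpoint")
    assert end.n_samples == 20


def test_bistable_landscape_minima_match_equilibria(table_params):
    p = table_params.replace(T42=2.0, T53=0.0)
    land = potential(estimate_pss(p, NoiseSpec(D=1e-6, seed=11),
                                  ensemble=80, t_end=2000.0, burn_in=1000.0,
                                  grid=80))
    stable = [e for e in find_equilibria(p, n_starts=512) if e.is_stable]
    assert len(land.minima) == len(stable) == 2
    for eq in stable:
        d = min(np.hypot(m[0] - eq.state[0], m[1] - eq.state[1])
                for m in land.minima)
        assert d <= land.bin_diagonal
    assert not land.ring_detected


def test_ensemble_doubling_keeps_minima(table_params):
    p = table_params.replace(T42=2.0, T53=0.0)
    spec = NoiseSpec(D=1e-6, seed=11)
    a = potential(estimate_pss(p, spec, ensemble=60, t_end=1500.0,
                               burn_in=800.0, grid=60))
    b = potential(estimate_pss(p, spec, ensemble=120, t_end=1500.0,
                               burn_in=800.0, grid=60))
    assert len(a.minima) == len(b.minima)
    for m in a.minima:
        assert min(np.hypot(m[0] - n[0], m[1] - n[1])
                   for n in b.minima) <= max(a.bin_diagonal, b.bin_diagonal)


def test_oscillatory_landscape_shows_ring(table_params):
    p = table_params.replace(T42=5.0, T53=4.0)
    land = potential(estimate_pss(p, NoiseSpec(D=1e-6, seed=11),
                                  ensemble=60, t_end=2000.0, burn_in=1000.0,
                                  grid=80))
    assert land.ring_detected


def test_landscape_save(tmp_path, table_params):
    p = table_params.replace(T42=1.0, T53=1.0)
    land = potential(estimate_pss(p, NoiseSpec(D=1e-6, seed=3), ensemble=10,
                                  t_end=400.0, burn_in=200.0, grid=30))
    land.save(tmp_path / "land")
    assert (tmp_path / "land.txt").exists()
    assert (tmp_path / "land.csv").exists()
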