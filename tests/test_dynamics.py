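"""Trajectories, attractor detection and the census."""

import numpy as np
import pytest

from bgct import (LimitCycle, ModelParameters, census, detect_attractor,
                  find_equilibria, integrate, oscillation_frequency)
from bgct.equilibria import Equilibrium


def test_integrate_stays_at_stable_equilibrium(table_params):
    p = table_params.replace(T42=1.0, T53=1.0)
    eq = find_equilibria(p, n_starts=256)[0]
    _t, X = integrate(p, eq.state, 200.0)
    assert np.max(np.abs(X - eq.state)) < 1e-6


def test_decoupled_mono_exponential_approach(decoupled_params):
    p = decoupled_params
    fp = p.R * p.I
    x0 = fp + 1.0
    t, X = integrate(p, x0, 60.0)
    tau = p.C * p.R  # per-population relaxation time, ms
    expect = fp + (x0 - fp) * np.exp(-t[:, None] / tau)
    np.testing.assert_allclose(X, expect, atol=1e-6)


def test_rk4_and_lsoda_agree(table_params):
    p = table_params.replace(T42=5.0, T53=4.0)
    x0 = np.full(7, 0.5)
    _t, Xa = integrate(p, x0, 500.0, method="lsoda")
    _t, Xb = integrate(p, x0, 500.0, method="rk4")
    assert np.max(np.abs(Xa - Xb)) < 1e-5


def test_integrate_rejects_bad_horizon(table_params):
    with pytest.raises(ValueError):
        integrate(table_params, np.zeros(7), -1.0)


def test_detect_constant_trajectory_is_equilibrium(decoupled_params):
    fp = decoupled_params.R * decoupled_params.I
    t = np.arange(0.0, 1000.0, 0.1)
    X = np.tile(fp, (len(t), 1))
    res = detect_attractor(t, X, decoupled_params)
    assert isinstance(res, Equilibrium)
    np.testing.assert_allclose(res.state, fp, atol=1e-8)


def test_detect_synthetic_oscillation(table_params):
    """An injected 40 ms sine must come back as a 25 Hz cycle."""
    t = np.arange(0.0, 2000.0, 0.1)
    X = np.tile(np.full(7, 1.0), (len(t), 1))
    X[:, 0] = 1.0 + 0.5 * np.sin(2 * np.pi * t / 40.0)
    res = detect_attractor(t, X, table_params)
    assert isinstance(res, LimitCycle)
    assert res.period == pytest.approx(40.0, rel=1e-3)
    assert res.frequency == pytest.approx(25.0, rel=1e-3)


def test_detect_decaying_spiral_is_not_a_cycle(table_params):
    """A slowly decaying oscillation must not be classified as a cycle."""
    t = np.arange(0.0, 2000.0, 0.1)
    X = np.tile(np.full(7, 1.0), (len(t), 1))
    X[:, 0] = 1.0 + 0.5 * np.exp(-t / 800.0) * np.sin(2 * np.pi * t / 40.0)
    res = detect_attractor(t, X, table_params)
    assert not isinstance(res, LimitCycle)


def test_oscillation_frequency_and_beta_flag():
    mk = lambda period: LimitCycle(period=period,
                                   envelope=np.array([[0.0] * 7, [1.0] * 7]),
                                   mean_state=np.full(7, 0.5))
    f, beta = oscillation_frequency(mk(50.0))
    assert f == pytest.approx(20.0) and beta
    f, beta = oscillation_frequency(mk(200.0))
    assert f == pytest.approx(5.0) and not beta
    assert mk(40.0).frequency * mk(40.0).period == pytest.approx(1000.0,
                                                                 rel=1e-9)


def test_cycle_dedup_rule():
    mk = lambda period, x1: LimitCycle(
        period=period, envelope=np.array([[0.0] * 7, [1.0] * 7]),
        mean_state=np.array([x1, 0, 0, 0, 0, 0, 0.0]))
    assert mk(60.0, 0.5).same_as(mk(60.5, 0.5))
    assert not mk(60.0, 0.5).same_as(mk(40.0, 0.5))       # period differs
    assert not mk(60.0, 0.5).same_as(mk(60.0, 0.7))       # mean differs


def test_census_decoupled_monostable(decoupled_params):
    aset = census(decoupled_params, n_starts=256)
    assert aset.regime_tag == "1SS+0LC"
    assert aset.exhaustive


def test_census_bistable_window(table_params):
    aset = census(table_params.replace(T42=2.0, T53=0.0), n_starts=512)
    assert aset.regime_tag == "2SS+0LC"
    assert aset.n_unstable == 1


def test_census_oscillatory_window(table_params):
    """Between the two Hopf points at T53=4 the cycle is the only attractor."""
    aset = census(table_params.replace(T42=5.0, T53=4.0), n_starts=512)
    assert aset.regime_tag == "0SS+1LC"
    c = aset.cycles[0]
    assert c.envelope[1, 0] > c.envelope[0, 0] + 0.1
    assert c.amplitude > 1.0


def test_census_two_coexisting_cycles(table_params):
    aset = census(table_params.replace(T42=6.7, T53=6.0), n_starts=512)
    assert len(aset.cycles) == 2
    periods = sorted(c.period for c in aset.cycles)
    assert periods[1] / periods[0] > 1.3   # genuinely distinct orbits


def test_census_is_deterministic(table_params):
    p = table_params.replace(T42=5.0, T53=4.0)
    a = census(p, n_starts=256)
    b = census(p, n_starts=256)
    assert a.regime_tag == b.regime_tag
    assert a.cycles[0].period == b.cycles[0].period


def test_census_fast_mode_agrees(table_params):
    for t42, t53 in [(2.0, 0.0), (5.0, 4.0), (4.5, 6.0)]:
        p = table_params.replace(T42=t42, T53=t53)
        assert census(p, fast=True, n_starts=512).regime_tag == \
            census(p, n_starts=512).regime_tag


def test_census_json_export(tmp_path, table_params):
    aset = census(table_params.replace(T42=5.0, T53=4.0), n_starts=256)
    out = aset.to_json(tmp_path / "census.json")
    assert out["regime_tag"] == "0SS+1LC"
    assert out["cycles"][0]["beta_band"] is True
    assert (tmp_path / "census.json").exists()
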