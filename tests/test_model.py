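"""Vector field: Hill response, drift sign pattern, exact Jacobian."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgct import ModelParameters, drift, hill_response, jacobian
from bgct.fixtures import PINNED_STATES, pinned_drift_table

# drift components at the pinned states, typical parameters with
# T42 = T53 = 1 (frozen regression values; must survive refactors)
PINNED_DRIFT = np.array([
    [0.02777777777777778, 0.18055555555555555, 0.16666666666666666,
     1.2222222222222223, 0.7777777777777777, 0.5555555555555556,
     0.3333333333333333],
    [-0.027445109780439136, 0.16977711244178306, 0.15588822355289417,
     0.9447771124417831, 0.6114437791084497, 0.21144377910844972,
     0.1669993346640053],
    [0.43528393334984533, 0.2974015829797396, 0.11717869542152277,
     0.3516844457272879, 0.11365184375261772, -1.0293669072112186,
     -1.1359516665072928],
    [-0.24426166227307822, 0.40080659023452714, -0.26178489346474093,
     1.3573540363837935, 0.5591112380119992, 0.419561854286537,
     -0.09792180345191971],
    [0.3109447771124418, 0.010763375210363557, 0.4958764823294587,
     0.38950229254914004, 0.8743086978381094, -0.4939454424484366,
     -0.003189699033305997],
])


@pytest.mark.parametrize("x, s, n, expected", [
    (0.0, 2.0, 2, 0.0),          # zero numerator
    (2.0, 2.0, 2, 0.5),          # x = s gives half activation
    (1.0, 2.0, 2, 0.2),          # 1 / (4 + 1) by hand
])
def test_hill_response_values(x, s, n, expected):
    assert hill_response(x, s, n) == pytest.approx(expected, abs=1e-15)


def test_hill_response_rejects_bad_input():
    with pytest.raises(ValueError):
        hill_response(np.nan, 2.0, 2)
    with pytest.raises(ValueError):
        hill_response(1.0, 0.0, 2)
    with pytest.raises(ValueError):
        hill_response(1.0, -1.0, 2)
    with pytest.raises(ValueError):
        hill_response(1.0, 2.0, 0)


@settings(max_examples=200, derandomize=True)
@given(x=st.floats(0.0, 1e6), y=st.floats(0.0, 1e6))
def test_hill_monotone_and_bounded(x, y):
    hx, hy = hill_response(x, 2.0, 2), hill_response(y, 2.0, 2)
    assert 0.0 <= hx < 1.0
    if x < y:
        assert hx <= hy


def test_hill_saturates():
    assert hill_response(1e9, 2.0, 2) == pytest.approx(1.0, abs=1e-9)


def test_default_parameters_are_typical_table(table_params):
    d = table_params.to_dict()
    assert all(d[f"C{i}"] == 3.60 for i in range(1, 8))
    assert all(d[f"R{i}"] == 1.67 for i in range(1, 8))
    expect = {"T16": 2.0, "T21": 1.4, "T26": 1.4, "T31": 1.4, "T36": 1.4,
              "T45": 3.0, "T47": 2.0, "T57": 1.0, "T64": 3.2, "T71": 1.8,
              "T75": 1.8, "s": 2.0, "n": 2, "Dinput": 0.6,
              "I1": 0.1, "I2": 0.05, "I3": 1.2, "I4": 4.4, "I5": 2.8,
              "I6": 2.0, "I7": 1.2}
    for k, v in expect.items():
        assert d[k] == v, k


def test_parameter_validation():
    with pytest.raises(ValueError):
        ModelParameters().replace(n=0)
    with pytest.raises(ValueError):
        ModelParameters().replace(s=-1.0)
    with pytest.raises(KeyError):
        ModelParameters().replace(T99=1.0)
    with pytest.raises(ValueError):
        ModelParameters(C=np.zeros(7))


def test_drift_at_origin_matches_hand_evaluation(table_params):
    # at x = 0 every Hill term vanishes: dx_i/dt = (I_i +/- Dinput)/C_i
    dx = drift(np.zeros(7), table_params)
    I, C, D = table_params.I, table_params.C, table_params.Dinput
    expect = (I + np.array([0, D, -D, 0, 0, 0, 0])) / C
    np.testing.assert_allclose(dx, expect, rtol=0, atol=1e-15)
    assert dx[0] == pytest.approx(0.1 / 3.60)


def test_decoupled_linear_decay(decoupled_params):
    p = decoupled_params
    fp = p.R * p.I
    np.testing.assert_allclose(drift(fp, p), 0.0, atol=1e-15)
    J = jacobian(np.array([1.0, -0.5, 2.0, 0.3, 4.0, 0.0, 1.5]), p)
    np.testing.assert_allclose(J, np.diag(-1.0 / (p.C * p.R)), atol=1e-15)


def test_drift_regression_pinned_states():
    np.testing.assert_allclose(
        pinned_drift_table().iloc[:, 7:].to_numpy(), PINNED_DRIFT,
        rtol=0, atol=1e-12)


def test_drift_sign_pattern(table_params):
    """Raising a presynaptic activity moves each target with the modeled sign."""
    x = np.full(7, 1.0)
    J = jacobian(x, table_params)
    # excitatory: thalamus->cortex, cortex->striatum, STN->GPi/GPe,
    # cortex->STN; inhibitory: striatum->GPi/GPe, GPe->GPi/STN, GPi->thalamus
    assert J[0, 5] > 0 and J[1, 0] > 0 and J[2, 0] > 0
    assert J[3, 6] > 0 and J[4, 6] > 0 and J[6, 0] > 0
    assert J[3, 1] < 0 and J[3, 4] < 0 and J[4, 2] < 0
    assert J[5, 3] < 0 and J[6, 4] < 0


def test_jacobian_matches_finite_differences(table_params, rng):
    p = table_params.replace(T42=3.0, T53=5.0)
    h = 1e-6
    for _ in range(100):
        x = rng.uniform(-2.0, 8.0, size=7)
        J = jacobian(x, p)
        Jfd = np.empty((7, 7))
        for k in range(7):
            e = np.zeros(7)
            e[k] = h
            Jfd[:, k] = (drift(x + e, p) - drift(x - e, p)) / (2 * h)
        scale = np.maximum(np.abs(J), 1.0)
        assert np.max(np.abs(J - Jfd) / scale) < 1e-6


def test_batched_drift_and_jacobian_agree(table_params, rng):
    X = rng.uniform(-1.0, 6.0, size=(11, 7))
    D = drift(X, table_params)
    J = jacobian(X, table_params)
    for k in range(len(X)):
        np.testing.assert_allclose(D[k], drift(X[k], table_params), atol=1e-14)
        np.testing.assert_allclose(J[k], jacobian(X[k], table_params),
                                   atol=1e-14)


def test_parameter_yaml_roundtrip(tmp_path, table_params):
    p = table_params.replace(T42=4.25, C3=2.5)
    path = tmp_path / "params.yaml"
    p.save(path)
    q = ModelParameters.load(path)
    assert q.to_dict() == p.to_dict()


def test_equilibrium_box_bounds_all_roots(table_params):
    from bgct import find_equilibria
    p = table_params.replace(T42=6.0, T53=6.0)
    box = p.equilibrium_box()
    for eq in find_equilibria(p, n_starts=512):
        assert np.all(eq.state >= box[0]) and np.all(eq.state <= box[1])


def test_pinned_states_match_fixture_module():
    assert PINNED_STATES.shape == (5, 7)
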