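"""Continuation: branch diagrams, codim-2 curves, regime maps."""

import numpy as np
import pytest

from bgct import ModelParameters, census, region_map, trace_branch_codim1
from bgct.bifurcation import _lead_complex_re
from bgct.model import jacobian


@pytest.fixture(scope="module")
def scan_t53_0(table_params=None):
    return trace_branch_codim1(ModelParameters().replace(T53=0.0), "T42",
                               (0.0, 7.0), with_envelope=False)


@pytest.fixture(scope="module")
def scan_t53_4():
    return trace_branch_codim1(ModelParameters().replace(T53=4.0), "T42",
                               (0.0, 7.0), with_envelope=True)


def test_bistable_slice_has_two_folds_and_one_hopf(scan_t53_0):
    assert scan_t53_0.n_folds == 2
    assert scan_t53_0.n_hopfs == 1
    f1, f2 = (f["param"] for f in scan_t53_0.folds)
    assert f1 < f2 < scan_t53_0.hopfs[0]["param"]


def test_monostable_slice_has_no_bifurcations():
    d = trace_branch_codim1(ModelParameters().replace(T53=3.0), "T42",
                            (0.0, 7.0), with_envelope=False)
    assert d.n_folds == 0 and d.n_hopfs == 0


def test_z_shaped_slice_two_hopfs_with_cycle_between(scan_t53_4):
    assert scan_t53_4.n_folds == 2
    assert scan_t53_4.n_hopfs == 2
    h1, h2 = (h["param"] for h in scan_t53_4.hopfs)
    env = scan_t53_4.cycle_envelope
    inside = env[(env.scan_value > h1 + 0.2) & (env.scan_value < h2 - 0.2)]
    assert len(inside) > 0
    assert (inside.x1_max > inside.x1_min).all()
    # Hopf points carry a genuine angular frequency
    assert all(h["omega"] > 1e-3 for h in scan_t53_4.hopfs)


def test_hopf_is_supercritical_by_amplitude_scaling(scan_t53_4):
    """Cycle amplitude grows as sqrt(mu - mu_H) past a supercritical Hopf."""
    mu_h = scan_t53_4.hopfs[0]["param"]
    dms = np.array([0.05, 0.1, 0.15, 0.2, 0.25, 0.3])
    amps = []
    for dm in dms:
        aset = census(ModelParameters().replace(T42=mu_h + dm, T53=4.0),
                      fast=True, n_starts=256, t_end=4000.0)
        assert aset.cycles
        amps.append(aset.cycles[0].amplitude)
    amps = np.array(amps)
    root = np.sqrt(dms)
    c = (root @ amps) / (root @ root)
    ss_res = np.sum((amps - c * root) ** 2)
    ss_tot = np.sum((amps - amps.mean()) ** 2)
    assert 1.0 - ss_res / ss_tot > 0.98


def test_stability_constant_between_bifurcations(scan_t53_0):
    """Along a branch the stability label only changes at detected points."""
    bif_params = sorted([f["param"] for f in scan_t53_0.folds]
                        + [h["param"] for h in scan_t53_0.hopfs])
    for br in scan_t53_0.branches:
        flips = np.nonzero(np.diff(br.stable.astype(int)))[0]
        for k in flips:
            p_flip = 0.5 * (br.pvals[k] + br.pvals[k + 1])
            assert min(abs(p_flip - b) for b in bif_params) < 0.05


def test_branch_diagram_export(tmp_path, scan_t53_0):
    scan_t53_0.save(tmp_path / "scan")
    assert (tmp_path / "scan.csv").exists()
    assert (tmp_path / "scan.json").exists()


def test_fold_curve_self_consistency():
    """Points on a traced codim-2 fold curve re-detect as codim-1 folds."""
    from bgct import trace_curve_codim2
    curves, _cusps = trace_curve_codim2(
        ModelParameters(), "T42", "T53",
        window=((0.0, 7.0), (0.0, 3.0)), curve_type="fold",
        seed_slices=(0.0, 1.0, 2.0))
    assert curves
    pts = curves[0].points
    sel = pts[(pts[:, 1] > 0.3) & (pts[:, 1] < 2.0)]
    probe = sel[len(sel) // 2]
    d = trace_branch_codim1(
        ModelParameters().replace(T53=float(probe[1])), "T42",
        (max(0.0, probe[0] - 0.7), min(7.0, probe[0] + 0.7)),
        n_seed_slices=5, with_envelope=False)
    assert d.folds
    assert min(abs(f["param"] - probe[0]) for f in d.folds) < 1e-3


def test_hopf_curve_crossing_flips_leading_pair():
    from bgct import trace_curve_codim2
    curves, _ = trace_curve_codim2(
        ModelParameters(), "T42", "T53",
        window=((0.0, 7.0), (3.5, 4.5)), curve_type="hopf",
        seed_slices=(4.0,))
    assert curves
    pts, states = curves[0].points, curves[0].states
    k = len(pts) // 2
    (t42, t53), x = pts[k], states[k]
    from bgct import find_equilibria
    res = []
    for dt in (-0.08, 0.08):
        eqs = find_equilibria(ModelParameters().replace(
            T42=t42 + dt, T53=t53), n_starts=512)
        eq = min(eqs, key=lambda e: np.linalg.norm(e.state - x))
        res.append(_lead_complex_re(eq.eigenvalues))
    assert res[0] * res[1] < 0


def test_cusp_separates_fold_pair_from_none():
    """Just below a cusp a codim-1 scan sees 2 folds, just above none."""
    from bgct import trace_curve_codim2
    curves, cusps = trace_curve_codim2(
        ModelParameters(), "T42", "T53",
        window=((0.0, 7.0), (0.0, 3.2)), curve_type="fold",
        seed_slices=(0.0, 1.0, 2.0))
    assert cusps
    cx, cy = cusps[0]
    lo = trace_branch_codim1(
        ModelParameters().replace(T53=cy - 0.25), "T42",
        (max(0.0, cx - 1.2), min(7.0, cx + 1.2)), n_seed_slices=5,
        with_envelope=False)
    hi = trace_branch_codim1(
        ModelParameters().replace(T53=cy + 0.25), "T42",
        (max(0.0, cx - 1.2), min(7.0, cx + 1.2)), n_seed_slices=5,
        with_envelope=False)
    assert lo.n_folds == 2
    assert hi.n_folds == 0


def test_degenerate_window_inside_monostable_region():
    rm = region_map(ModelParameters(), "T42", "T53",
                    window=((0.4, 1.4), (0.4, 1.4)), resolution=21,
                    geometry_resolution=41, label_lattice=False)
    assert rm.region_count == 1
    assert rm.regions[0]["tag"] == "1SS+0LC"
    assert not rm.fold_curves and not rm.hopf_curves


def test_no_oscillation_at_small_weights():
    """Cycles need strong direct/indirect pathways: none below 2/2."""
    for t42 in np.linspace(0.0, 2.0, 3):
        for t53 in np.linspace(0.0, 2.0, 3):
            aset = census(ModelParameters().replace(T42=float(t42),
                                                    T53=float(t53)),
                          fast=True, n_starts=256)
            assert not aset.cycles
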