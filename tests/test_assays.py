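"""Binding-assay simulators and fitters: recovery, oracles, invariants."""

import numpy as np
import pytest

from graftkit.assays import (AssayDataset, FitError, association_closed_form,
                             default_sck_schedule, fit_elisa, fit_saturation,
                             fit_sck_spr, integrate_binding, lindmo_fit,
                             simulate_elisa, simulate_lindmo,
                             simulate_saturation, simulate_sck)

ELISA_CONCS = np.array([0.05, 0.1, 0.2, 0.5, 1, 2, 5, 10, 20, 50, 100, 200])  # nM
SAT_CONCS = np.array([1, 2, 5, 10, 15, 30, 60, 120, 240])                     # nM
CELLS = np.geomspace(1e9, 1e11, 6)                                            # cells/L


def test_elisa_zero_noise_recovers_kd_to_4_digits():
    data = simulate_elisa(1.3, 2.0, 0.05, ELISA_CONCS)
    fit = fit_elisa(data)
    assert fit.k_d == pytest.approx(1.3, rel=1e-4)
    assert fit.a_max == pytest.approx(2.0, rel=1e-4)
    assert fit.plateau_reached


def test_elisa_noisy_median_error_below_ten_percent():
    errors = []
    for seed in range(40):
        data = simulate_elisa(1.3, 2.0, 0.05, ELISA_CONCS, noise_cv=0.05, seed=seed)
        errors.append(abs(fit_elisa(data).k_d - 1.3) / 1.3)
    assert float(np.median(errors)) < 0.10


def test_elisa_constant_signal_rejected():
    data = AssayDataset(ELISA_CONCS, np.full(len(ELISA_CONCS), 0.7), "elisa")
    with pytest.raises(FitError):
        fit_elisa(data)


def test_elisa_simulation_is_seeded():
    a = simulate_elisa(1.3, 2.0, 0.0, ELISA_CONCS, noise_cv=0.05, seed=7)
    b = simulate_elisa(1.3, 2.0, 0.0, ELISA_CONCS, noise_cv=0.05, seed=7)
    np.testing.assert_array_equal(a.y, b.y)


def test_elisa_more_points_reduce_rmse():
    few = np.geomspace(0.05, 200, 6)
    many = np.geomspace(0.05, 200, 24)
    def rmse(concs):
        errs = [(fit_elisa(simulate_elisa(1.3, 2.0, 0.05, concs, 0.05, s)).k_d - 1.3)
                for s in range(25)]
        return float(np.sqrt(np.mean(np.square(errs))))
    assert rmse(many) < rmse(few)


def test_integrator_matches_closed_form_association():
    t = np.linspace(0.0, 600.0, 121)
    c = 2e-9
    numeric = integrate_binding(t, [(0.0, 1e9, c)], 1e6, 3.4e-4, 100.0)
    analytic = association_closed_form(t, c, 1e6, 3.4e-4, 100.0)
    rel = np.abs(numeric[1:] - analytic[1:]) / analytic[1:]
    assert rel.max() < 1e-6


def test_spr_single_cycle_round_trip():
    schedule, t_end = default_sck_schedule([0.5e-9, 1e-9, 2e-9, 4e-9, 8e-9])
    data = simulate_sck(schedule, t_end, 1e6, 3.4e-4, 100.0, dt=2.0)
    fit = fit_sck_spr(data)
    assert fit.k_on == pytest.approx(1e6, rel=1e-3)
    assert fit.k_off == pytest.approx(3.4e-4, rel=1e-3)
    assert fit.k_d == pytest.approx(0.34e-9, rel=1e-3)


def test_spr_kd_identity_holds_exactly():
    schedule, t_end = default_sck_schedule([1e-9, 4e-9])
    data = simulate_sck(schedule, t_end, 5e5, 1e-3, 80.0, dt=2.0)
    fit = fit_sck_spr(data)
    assert fit.k_d == fit.k_off / fit.k_on  # identity by construction


def test_spr_zero_koff_flagged_unidentifiable():
    schedule, t_end = default_sck_schedule([2e-9])
    data = simulate_sck(schedule, t_end, 1e6, 0.0, 100.0, dt=2.0)
    # monotone saturating curve by construction
    assert np.all(np.diff(data.y) >= -1e-9)
    fit = fit_sck_spr(data)
    assert not fit.k_off_identifiable


def test_saturation_zero_noise_exact():
    data = simulate_saturation(15.0, 1000.0, SAT_CONCS)
    fit = fit_saturation(data)
    assert fit.k_d == pytest.approx(15.0, rel=1e-6)
    assert fit.b_max == pytest.approx(1000.0, rel=1e-6)


def test_saturation_half_maximum_at_kd():
    data = simulate_saturation(15.0, 1000.0, np.array([15.0, 1, 5, 50, 200]))
    assert data.y[0] == pytest.approx(500.0)


def test_saturation_noisy_median_bias_below_ten_percent():
    biases = []
    triplicate = np.repeat(SAT_CONCS, 3)  # study protocol: triplicate
    for seed in range(40):
        data = simulate_saturation(15.0, 1000.0, triplicate, noise_cv=0.10, seed=seed)
        biases.append(abs(fit_saturation(data).k_d - 15.0) / 15.0)
    assert float(np.median(biases)) < 0.10


def test_lindmo_ideal_tracer_with_antigen_excess():
    data = simulate_lindmo(1.0, 1e-12, CELLS * 100)
    res = lindmo_fit(data)
    assert res.intercept == pytest.approx(1.0, rel=1e-3)
    assert res.immunoreactive_fraction == pytest.approx(1.0, rel=1e-3)


def test_lindmo_zero_noise_recovers_fraction():
    data = simulate_lindmo(0.73, 15e-9, CELLS)
    res = lindmo_fit(data)
    assert res.immunoreactive_fraction == pytest.approx(0.73, rel=1e-3)
    assert not res.flagged


def test_lindmo_noisy_recovery_within_tolerance():
    fracs = [lindmo_fit(simulate_lindmo(0.73, 15e-9, np.repeat(CELLS, 3),
                                        noise_cv=0.05, seed=s)).immunoreactive_fraction
             for s in range(40)]
    assert abs(float(np.mean(fracs)) - 0.73) < 0.05


def test_lindmo_duplicates_averaged():
    base = simulate_lindmo(0.73, 15e-9, CELLS)
    doubled = AssayDataset(np.repeat(base.x, 2), np.repeat(base.y, 2), "lindmo")
    a, b = lindmo_fit(base), lindmo_fit(doubled)
    assert a.immunoreactive_fraction == pytest.approx(b.immunoreactive_fraction)


def test_lindmo_invalid_fractions_rejected():
    with pytest.raises(FitError):
        lindmo_fit(AssayDataset(CELLS, np.full(len(CELLS), 1.2), "lindmo"))


@pytest.mark.parametrize("scale", [0.1, 1.0, 250.0])
def test_fitters_are_scale_equivariant(scale):
    """Scaling y rescales amplitudes but leaves K_D untouched."""
    data = simulate_elisa(1.3, 2.0, 0.0, ELISA_CONCS)
    scaled = AssayDataset(data.x, data.y * scale, "elisa")
    f0, f1 = fit_elisa(data), fit_elisa(scaled)
    assert f1.k_d == pytest.approx(f0.k_d, rel=1e-6)
    assert f1.a_max == pytest.approx(f0.a_max * scale, rel=1e-6)

    sat = simulate_saturation(15.0, 1000.0, SAT_CONCS)
    s0 = fit_saturation(sat)
    s1 = fit_saturation(AssayDataset(sat.x, sat.y * scale, "saturation"))
    assert s1.k_d == pytest.approx(s0.k_d, rel=1e-6)
    assert s1.b_max == pytest.approx(s0.b_max * scale, rel=1e-6)
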