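"""Stochastic gating simulator: analytic dwell statistics and rendering."""

import numpy as np
import pytest
from scipy import stats

from chanpopen.cluster_popen import segment_clusters
from chanpopen.dwells import DwellSequence
from chanpopen.filtering import RISE_FC
from chanpopen.gating_sim import (
    HUMAN_ALPHA1_HILL,
    STANDARD_CONC_UM,
    GatingRates,
    SimConfig,
    _rate_matrix,
    generate_crc_dataset,
    rates_from_mechanism,
    render_trace,
    simulate_dwells,
)
from chanpopen.dose_response import hill_curve, rundown_check
from chanpopen.mechanism import FlipMechanism, eff_from_EF


def stationary_open_fraction(rates: GatingRates) -> float:
    """Matrix oracle: conditional open occupancy among non-desensitized states.

    Solves pi Q = 0 for the full 4-state chain and conditions on the three
    active states; independent of the simulator's trajectory machinery.
    """
    q = _rate_matrix(rates)
    Q = q - np.diag(q.sum(axis=1))
    # stationary distribution: left null vector of Q
    w, v = np.linalg.eig(Q.T)
    pi = np.real(v[:, np.argmin(np.abs(w))])
    pi = pi / pi.sum()
    active = pi[:3]
    return float(active[2] / active.sum())


def test_rates_from_mechanism_products():
    mech = FlipMechanism(E=38.0, F=8.0)
    rates = rates_from_mechanism(mech, gamma=1000.0, alpha=2000.0)
    assert rates.delta == pytest.approx(8000.0)
    assert rates.beta == pytest.approx(76000.0)
    assert eff_from_EF(rates.E, rates.F) == pytest.approx(mech.eff, rel=1e-12)
    unit = rates_from_mechanism(FlipMechanism(E=1.0, F=1.0))
    assert unit.delta == unit.gamma and unit.beta == unit.alpha


def test_rates_validation():
    with pytest.raises(ValueError):
        GatingRates(delta=1, gamma=-1, beta=1, alpha=1)
    with pytest.raises(ValueError):
        GatingRates(delta=1, gamma=1, beta=1, alpha=1, desens_from="resting")


def test_seed_determinism():
    rates = rates_from_mechanism(FlipMechanism(E=0.956, F=8.0))
    d1 = simulate_dwells(rates, 20.0, seed=11, sub_prob=0.02)
    d2 = simulate_dwells(rates, 20.0, seed=11, sub_prob=0.02)
    assert np.array_equal(d1.durations, d2.durations)
    assert np.array_equal(d1.state_class, d2.state_class)
    assert np.array_equal(d1.conductance_class, d2.conductance_class)
    cfg = SimConfig(duration=20.0, seed=11)
    t1 = render_trace(d1, cfg)
    t2 = render_trace(d2, cfg)
    assert np.array_equal(t1.samples, t2.samples)
    d3 = simulate_dwells(rates, 20.0, seed=12, sub_prob=0.02)
    assert len(d3) != len(d1) or not np.array_equal(d1.durations, d3.durations)


def test_dwells_cover_requested_window():
    rates = rates_from_mechanism(FlipMechanism(E=0.956, F=8.0))
    dwells = simulate_dwells(rates, 30.0, seed=3)
    assert dwells.total_duration == pytest.approx(30.0, abs=1e-9)


def test_open_dwell_mean_matches_analytic_sojourn(taurine_recording):
    """Open sojourns are exponential with mean 1/(alpha + d_plus)."""
    _, _, dwells, _ = taurine_recording
    rates = rates_from_mechanism(FlipMechanism(E=0.956, F=8.0))
    open_dur = dwells.durations[np.asarray(dwells.state_class == "open")]
    assert open_dur.size > 10_000
    expected = 1.0 / (rates.alpha + rates.d_plus)
    se = open_dur.std(ddof=1) / np.sqrt(open_dur.size)
    assert abs(open_dur.mean() - expected) < 3 * se


def test_open_dwells_are_exponential(taurine_recording):
    _, _, dwells, _ = taurine_recording
    open_dur = dwells.durations[np.asarray(dwells.state_class == "open")]
    # KS test against the exponential with the empirical mean
    d, p = stats.kstest(open_dur / open_dur.mean(), "expon")
    assert p > 1e-3


def test_within_cluster_open_occupancy_matches_flip_model(taurine_recording):
    """Raw-dwell cluster P_open agrees with EF/(EF+F+1) and the matrix oracle."""
    mech, _, dwells, _ = taurine_recording
    rates = rates_from_mechanism(mech)
    oracle = stationary_open_fraction(rates)
    # desensitization flux perturbs active-state occupancies at O(d_plus/alpha),
    # so the oracle sits within ~0.1% of the flip formula ...
    assert oracle == pytest.approx(mech.popen_max, rel=2e-3)
    # ... and converges to it exactly as d_plus -> 0
    slow = rates_from_mechanism(mech, d_plus=1e-6)
    assert stationary_open_fraction(slow) == pytest.approx(mech.popen_max, rel=1e-8)
    clusters = segment_clusters(dwells)
    popens = np.array([c.popen for c in clusters])
    se = popens.std(ddof=1) / np.sqrt(popens.size)
    assert abs(popens.mean() - oracle) < max(3 * se, 0.02)


def test_no_desensitization_limit_gives_single_active_period():
    rates = GatingRates(
        delta=8000.0, gamma=1000.0, beta=1912.0, alpha=2000.0,
        d_plus=1e-9, d_minus=10.0,
    )
    dwells = simulate_dwells(rates, 5.0, seed=5)
    assert np.count_nonzero(dwells.state_class == "desensitized") <= 1


def test_cluster_count_scales_with_duration():
    rates = rates_from_mechanism(FlipMechanism(E=0.956, F=8.0))
    n_short = np.count_nonzero(
        simulate_dwells(rates, 50.0, seed=2).state_class == "desensitized"
    )
    n_long = np.count_nonzero(
        simulate_dwells(rates, 200.0, seed=2).state_class == "desensitized"
    )
    assert 2.0 < n_long / n_short < 6.0


def test_render_all_shut_is_zero():
    dwells = DwellSequence.from_records([("shut", "zero", 0.05)])
    cfg = SimConfig(duration=0.05, noise_sd=0.0, seed=0)
    trace = render_trace(dwells, cfg)
    assert np.all(trace.samples == 0.0)
    assert trace.fs == pytest.approx(cfg.fs_internal / 3)


def test_render_step_plateau_and_rise_time():
    """A 10 ms opening renders at 5 pA with the Gaussian step rise 0.3396/fc."""
    dwells = DwellSequence.from_records(
        [("shut", "zero", 0.02), ("open", "full", 0.01), ("shut", "zero", 0.02)]
    )
    cfg = SimConfig(duration=0.05, noise_sd=0.0, sub_prob=0.0, seed=0)
    trace = render_trace(dwells, cfg)
    t = trace.times
    mid = (t > 0.022) & (t < 0.028)
    assert np.allclose(trace.samples[mid], cfg.amplitude, rtol=0.01)
    # 10-90% rise time across the leading edge
    edge = trace.samples[(t > 0.018) & (t < 0.023)]
    te = t[(t > 0.018) & (t < 0.023)]
    t10 = np.interp(0.1 * cfg.amplitude, edge, te)
    t90 = np.interp(0.9 * cfg.amplitude, edge, te)
    expected = RISE_FC / cfg.fc
    assert abs((t90 - t10) - expected) < 2.0 / trace.fs


def test_render_preserves_mean_current():
    dwells = DwellSequence.from_records(
        [("shut", "zero", 0.01), ("open", "full", 0.02), ("shut", "zero", 0.01)]
    )
    cfg = SimConfig(duration=0.04, noise_sd=0.0, seed=0)
    trace = render_trace(dwells, cfg)
    ideal_mean = cfg.amplitude * 0.02 / 0.04
    assert trace.samples.mean() == pytest.approx(ideal_mean, rel=0.02)


def test_subconductance_dwells_render_at_sub_level():
    dwells = DwellSequence.from_records(
        [("shut", "zero", 0.02), ("open", "sub", 0.01), ("shut", "zero", 0.02)]
    )
    cfg = SimConfig(duration=0.05, noise_sd=0.0, seed=0)
    trace = render_trace(dwells, cfg)
    assert trace.samples.max() == pytest.approx(cfg.sub_amplitude, rel=0.02)


def test_sim_config_validation():
    with pytest.raises(ValueError):
        SimConfig(fc=20_000.0, fs_out=25_000.0)
    with pytest.raises(ValueError):
        SimConfig(sub_amplitude=6.0)
    with pytest.raises(ValueError):
        SimConfig(sub_prob=1.0)


# --- whole-cell CRC generator --------------------------------------------

def test_crc_noiseless_lies_on_hill_curve(noiseless_crc):
    """With zero noise and drift, responses are exactly scale × Hill."""
    cell = noiseless_crc[noiseless_crc["cell_id"] == "cell00"]
    std = cell[cell["is_standard"]]
    y_gly, ec50_gly, nh_gly = HUMAN_ALPHA1_HILL["glycine"]
    scale = std["peak_current_nA"].iloc[0] / float(
        hill_curve(STANDARD_CONC_UM, y_gly, ec50_gly, nh_gly)
    )
    test_rows = cell[~cell["is_standard"]]
    for _, row in test_rows.iterrows():
        y, ec50, nh = HUMAN_ALPHA1_HILL[row["agonist"]]
        expected = scale * float(hill_curve(row["concentration_uM"], y, ec50, nh))
        assert row["peak_current_nA"] == pytest.approx(expected, rel=1e-9)


def test_crc_response_at_ec50_is_half_max():
    data = generate_crc_dataset(
        hill={"glycine": (1.0, 240.0, 1.57)},
        concentrations={"glycine": [240.0]},
        n_cells=1,
        noise_cv=0.0,
        rundown_rate=0.0,
        seed=1,
    )
    row = data[(~data["is_standard"])].iloc[0]
    std = data[data["is_standard"]]["peak_current_nA"].iloc[0]
    y, ec50, nh = 1.0, 240.0, 1.57
    saturating = float(hill_curve(STANDARD_CONC_UM, y, ec50, nh))
    assert row["peak_current_nA"] / (std / saturating) == pytest.approx(0.5, rel=1e-9)


def test_crc_rundown_constructed_violation_fails_screen():
    data = generate_crc_dataset(
        n_cells=2, noise_cv=0.0, rundown_rate=0.40, seed=4
    )
    for _, cell in data.groupby("cell_id"):
        assert not rundown_check(cell).passed


def test_crc_determinism_and_schema():
    a = generate_crc_dataset(n_cells=2, seed=9)
    b = generate_crc_dataset(n_cells=2, seed=9)
    assert a.equals(b)
    assert list(a.columns) == [
        "cell_id", "order", "agonist", "concentration_uM",
        "peak_current_nA", "is_standard",
    ]
    # first and last application of every cell are standards
    for _, cell in a.groupby("cell_id"):
        cell = cell.sort_values("order")
        assert bool(cell["is_standard"].iloc[0]) and bool(cell["is_standard"].iloc[-1])


def test_crc_empty_concentrations_rejected():
    with pytest.raises(ValueError):
        generate_crc_dataset(concentrations={"glycine": []})
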