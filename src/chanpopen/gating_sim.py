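"""Synthetic single-channel and whole-cell data generation.

Emulates cell-attached recordings from glycine receptors: a single channel
cycles through a 4-state scheme

    desensitized (D)  <-  open (O)  <->  flipped (Fl)  <->  resting (R)
          |______________________________________________________^

where the flipped/resting equilibrium is F = delta/gamma and the
open/flipped equilibrium is E = beta/alpha.  Because desensitized sojourns
are long (seconds) and gating within an activation is fast (sub-ms to ms),
activity appears as dense clusters of openings separated by silent gaps —
the structure exploited by cluster-based open-probability analysis.  Within
a cluster the equilibrium open occupancy is E·F/(E·F+F+1), the flip-model
maximum P_open.

Traces are rendered the way an acquisition chain would produce them:
piecewise-constant current at a high internal rate, Gaussian-filtered at a
stated −3 dB cutoff, decimated to the output rate, plus baseline noise.
Rare ~1 pA subconductance openings can be injected; the idealizer's
half-amplitude threshold classifies them as shut, as threshold-crossing
analysis does.

A second generator produces whole-cell concentration–response datasets with
interleaved saturating-glycine standards and run-down drift, for exercising
the dose–response pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dwells import DwellSequence, Trace
from .filtering import gaussian_lowpass
from .mechanism import FlipMechanism

__all__ = [
    "GatingRates",
    "SimConfig",
    "rates_from_mechanism",
    "simulate_dwells",
    "render_trace",
    "simulate_recording",
    "generate_crc_dataset",
]

# state indices of the embedded chain
_R, _FL, _O, _D = 0, 1, 2, 3
_STATE_CLASS = np.array(["shut", "shut", "open", "desensitized"], dtype=object)


@dataclass(frozen=True)
class GatingRates:
    """Transition rates (s⁻¹) of the 4-state gating scheme.

    ``delta``/``gamma`` are the flipping/unflipping rates (R↔Fl), ``beta``/
    ``alpha`` the opening/closing rates (Fl↔O).  Desensitization is entered
    from the state named by ``desens_from`` at rate ``d_plus`` and left at
    ``d_minus`` (D→R).  Defaults give ~0.5 s clusters separated by ~4 s
    silences.
    """

    delta: float
    gamma: float
    beta: float
    alpha: float
    d_plus: float = 2.0
    d_minus: float = 0.25
    desens_from: str = "open"

    def __post_init__(self) -> None:
        for name in ("delta", "gamma", "beta", "alpha", "d_plus", "d_minus"):
            if not getattr(self, name) > 0:
                raise ValueError(f"rate {name} must be positive")
        if self.desens_from not in ("open", "flipped"):
            raise ValueError("desens_from must be 'open' or 'flipped'")

    @property
    def E(self) -> float:
        return self.beta / self.alpha

    @property
    def F(self) -> float:
        return self.delta / self.gamma

    @property
    def mechanism(self) -> FlipMechanism:
        return FlipMechanism(E=self.E, F=self.F)


@dataclass(frozen=True)
class SimConfig:
    """Rendering settings for synthetic recordings.

    Defaults match a typical glycine-receptor cell-attached recording:
    ~5 pA full openings, rare ~1 pA subconductance events, 3 kHz Gaussian
    filtering and 33.3 kHz output sampling (simulated at 100 kHz), 0.5 pA
    RMS baseline noise.
    """

    duration: float = 60.0
    amplitude: float = 5.0  # pA, full open level
    sub_amplitude: float = 1.0  # pA, subconductance level
    sub_prob: float = 0.02  # fraction of openings at the sub level
    noise_sd: float = 0.5  # pA RMS
    fs_internal: float = 100_000.0  # Hz, simulation rate
    fs_out: float = 100_000.0 / 3.0  # Hz, output rate (33.3 kHz)
    fc: float = 3_000.0  # Hz, Gaussian −3 dB cutoff
    n_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not self.amplitude > self.sub_amplitude > 0:
            raise ValueError("require amplitude > sub_amplitude > 0")
        if not 0 <= self.sub_prob < 1:
            raise ValueError("sub_prob must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.fs_out < 2 * self.fc:
            raise ValueError("fs_out must be at least 2*fc")
        if self.fc > self.fs_internal / 2:
            raise ValueError("fc exceeds the internal Nyquist frequency")
        decim = self.fs_internal / self.fs_out
        if abs(decim - round(decim)) > 1e-9:
            raise ValueError("fs_internal must be an integer multiple of fs_out")


def rates_from_mechanism(
    mech: FlipMechanism,
    gamma: float = 1_000.0,
    alpha: float = 2_000.0,
    d_plus: float = 2.0,
    d_minus: float = 0.25,
    desens_from: str = "open",
) -> GatingRates:
    """Anchor transition rates to a mechanism's equilibrium constants.

    The equilibrium description fixes only the ratios delta/gamma = F and
    beta/alpha = E; the backward rates ``gamma`` and ``alpha`` set the time
    scale.  Defaults (1,000 and 2,000 s⁻¹) put shut and open dwells in the
    tens of µs to ms range, resolvable after 3 kHz filtering.
    """
    return GatingRates(
        delta=mech.F * gamma,
        gamma=gamma,
        beta=mech.E * alpha,
        alpha=alpha,
        d_plus=d_plus,
        d_minus=d_minus,
        desens_from=desens_from,
    )


def _rate_matrix(rates: GatingRates) -> np.ndarray:
    """Off-diagonal rate matrix q[i, j] of the 4-state scheme."""
    q = np.zeros((4, 4))
    q[_R, _FL] = rates.delta
    q[_FL, _R] = rates.gamma
    q[_FL, _O] = rates.beta
    q[_O, _FL] = rates.alpha
    if rates.desens_from == "open":
        q[_O, _D] = rates.d_plus
    else:
        q[_FL, _D] = rates.d_plus
    q[_D, _R] = rates.d_minus
    return q


def simulate_dwells(
    rates: GatingRates,
    duration: float,
    seed: int | np.random.SeedSequence = 0,
    sub_prob: float = 0.0,
) -> DwellSequence:
    """Exact stochastic simulation of the gating scheme.

    The continuous-time Markov chain is simulated state by state: sojourns
    are exponential with the state's total exit rate, and the successor is
    drawn with probability proportional to the outgoing rates.  The chain
    starts desensitized; the final sojourn is truncated at ``duration`` so
    the sequence covers the window exactly.  Each opening is independently
    tagged as a subconductance event with probability ``sub_prob``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    chain_seed, sub_seed = ss.spawn(2)
    rng = np.random.default_rng(chain_seed)

    q = _rate_matrix(rates)
    exit_rate = q.sum(axis=1)
    # per-state cumulative successor probabilities for inverse-CDF draws
    cum_prob = np.cumsum(q / exit_rate[:, None], axis=1)

    states: list[int] = []
    sojourns: list[float] = []
    t = 0.0
    state = _D
    block = 1 << 14
    exp_pool = rng.exponential(size=block)
    uni_pool = rng.random(size=block)
    i = 0
    while t < duration:
        if i >= block:
            exp_pool = rng.exponential(size=block)
            uni_pool = rng.random(size=block)
            i = 0
        dt = exp_pool[i] / exit_rate[state]
        states.append(state)
        sojourns.append(dt)
        t += dt
        state = int(np.searchsorted(cum_prob[state], uni_pool[i], side="right"))
        i += 1
    sojourns[-1] -= t - duration  # truncate at the window edge
    if sojourns[-1] <= 0:  # numerically possible for a boundary-grazing sojourn
        states.pop()
        sojourns.pop()

    state_arr = np.asarray(states, dtype=np.intp)
    state_class = _STATE_CLASS[state_arr]
    conductance = np.where(state_arr == _O, "full", "zero").astype(object)
    if sub_prob > 0:
        sub_rng = np.random.default_rng(sub_seed)
        is_open = state_arr == _O
        sub_draw = sub_rng.random(int(is_open.sum())) < sub_prob
        idx = np.flatnonzero(is_open)[sub_draw]
        conductance[idx] = "sub"
    seq = DwellSequence(state_class, conductance, np.asarray(sojourns, float))
    return seq.merged()


def render_trace(dwells: DwellSequence, config: SimConfig) -> Trace:
    """Render an idealized dwell sequence into a noisy filtered trace.

    The ideal piecewise-constant current (0 pA shut/desensitized,
    ``amplitude`` pA full openings, ``sub_amplitude`` pA subconductance
    dwells) is sampled at ``fs_internal``, convolved with a truncated
    Gaussian kernel of −3 dB cutoff ``fc``, decimated to ``fs_out``, and
    Gaussian baseline noise of SD ``noise_sd`` is added.  All settings are
    recorded in the trace metadata.
    """
    levels = np.zeros(len(dwells), dtype=np.float32)
    levels[np.asarray(dwells.state_class == "open")] = config.amplitude
    levels[np.asarray(dwells.conductance_class == "sub")] = config.sub_amplitude

    edges = np.concatenate(([0.0], np.cumsum(dwells.durations)))
    sample_edges = np.round(edges * config.fs_internal).astype(np.int64)
    counts = np.diff(sample_edges)
    ideal = np.repeat(levels, counts)
    if ideal.size == 0:
        raise ValueError("dwell sequence too short to render at fs_internal")

    filtered = gaussian_lowpass(ideal, config.fc, config.fs_internal)
    decim = int(round(config.fs_internal / config.fs_out))
    out = filtered[::decim].astype(np.float32)

    noise_seed = np.random.SeedSequence(config.seed).spawn(3)[2]
    if config.noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        out = out + rng.normal(0.0, config.noise_sd, out.size).astype(np.float32)

    fs_out = config.fs_internal / decim
    return Trace(
        samples=out,
        fs=fs_out,
        fc=config.fc,
        metadata={
            "generator": "chanpopen.gating_sim",
            "amplitude_pA": config.amplitude,
            "sub_amplitude_pA": config.sub_amplitude,
            "noise_sd_pA": config.noise_sd,
            "fs_internal_Hz": config.fs_internal,
            "fc_Hz": config.fc,
            "seed": config.seed,
        },
    )


def simulate_recording(
    mech: FlipMechanism,
    config: SimConfig = SimConfig(),
    rates: GatingRates | None = None,
) -> tuple[DwellSequence, Trace]:
    """Simulate dwells for a mechanism and render them into a trace.

    One master seed (``config.seed``) fans out deterministically to the
    chain, subconductance and noise streams.
    """
    if rates is None:
        rates = rates_from_mechanism(mech)
    ss = np.random.SeedSequence(config.seed)
    dwells = simulate_dwells(rates, config.duration, seed=ss, sub_prob=config.sub_prob)
    trace = render_trace(dwells, config)
    return dwells, trace


# ---------------------------------------------------------------------------
# whole-cell concentration–response generator

#: typical human α1 GlyR whole-cell pharmacology used as generator defaults:
#: (relative maximum response, EC50 in µM, Hill coefficient) per agonist
HUMAN_ALPHA1_HILL: Mapping[str, tuple[float, float, float]] = {
    "glycine": (1.0, 240.0, 1.57),
    "beta-alanine": (0.73, 860.0, 1.5),
    "taurine": (0.25, 2000.0, 1.30),
    "GABA": (0.017, 61000.0, 1.32),
}

STANDARD_AGONIST = "glycine"
STANDARD_CONC_UM = 10_000.0  # 10 mM glycine standard


def _hill(conc: np.ndarray, y_max: float, ec50: float, n_h: float) -> np.ndarray:
    c = np.power(conc, n_h)
    return y_max * c / (c + ec50**n_h)


def generate_crc_dataset(
    hill: Mapping[str, tuple[float, float, float]] = HUMAN_ALPHA1_HILL,
    n_cells: int = 6,
    concentrations: Mapping[str, Sequence[float]] | Sequence[float] | None = None,
    noise_cv: float = 0.1,
    rundown_rate: float = 0.1,
    seed: int = 0,
    i_max_nA: float = 13.2,
    cell_cv: float = 0.3,
    standard_every: int = 3,
) -> pd.DataFrame:
    """Generate per-cell whole-cell concentration–response tables.

    Each cell applies, in order: a 10 mM glycine standard, the test
    concentrations of each agonist (ascending), a standard after every
    ``standard_every`` test applications, and a final standard.  Responses
    follow the Hill curve scaled by a per-cell maximal current (log-normal
    around ``i_max_nA`` with CV ``cell_cv``), with multiplicative log-normal
    noise of CV ``noise_cv`` and a linear run-down of total fractional size
    ``rundown_rate`` across the application sequence.

    Returns a tidy frame with columns ``cell_id, order, agonist,
    concentration_uM, peak_current_nA, is_standard``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if concentrations is None:
        concentrations = {
            ag: np.geomspace(ec50 / 8.0, ec50 * 40.0, 6)
            for ag, (_, ec50, _) in hill.items()
        }
    elif not isinstance(concentrations, Mapping):
        concentrations = {ag: list(concentrations) for ag in hill}
    for ag, concs in concentrations.items():
        if len(concs) == 0:
            raise ValueError(f"empty concentration list for {ag!r}")
        if np.any(np.asarray(concs, float) <= 0):
            raise ValueError(f"non-positive concentration for {ag!r}")
    if STANDARD_AGONIST not in hill:
        raise ValueError(f"hill mapping must include {STANDARD_AGONIST!r}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    log_sd = np.sqrt(np.log1p(noise_cv**2))
    rows: list[dict] = []
    for cell in range(n_cells):
        scale = i_max_nA * rng.lognormal(-0.5 * np.log1p(cell_cv**2), np.sqrt(np.log1p(cell_cv**2)))
        # build the application schedule
        schedule: list[tuple[str, float, bool]] = [
            (STANDARD_AGONIST, STANDARD_CONC_UM, True)
        ]
        since_standard = 0
        for ag in concentrations:
            for c in np.sort(np.asarray(concentrations[ag], float)):
                schedule.append((ag, float(c), False))
                since_standard += 1
                if since_standard >= standard_every:
                    schedule.append((STANDARD_AGONIST, STANDARD_CONC_UM, True))
                    since_standard = 0
        if not schedule[-1][2]:
            schedule.append((STANDARD_AGONIST, STANDARD_CONC_UM, True))

        n_app = len(schedule)
        for order, (ag, conc, is_std) in enumerate(schedule):
            y_max, ec50, n_h = hill[ag]
            ideal = scale * float(_hill(np.asarray(conc), y_max, ec50, n_h))
            drift = 1.0 - rundown_rate * (order / (n_app - 1) if n_app > 1 else 0.0)
            noisy = ideal * drift
            if noise_cv > 0:
                noisy *= rng.lognormal(-0.5 * log_sd**2, log_sd)
            rows.append(
                {
                    "cell_id": f"cell{cell:02d}",
                    "order": order,
                    "agonist": ag,
                    "concentration_uM": conc,
                    "peak_current_nA": noisy,
                    "is_standard": is_std,
                }
            )
    return pd.DataFrame(rows)
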