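"""Synthetic smFRET data with known ground truth.

Two generators mirror the two experimental geometries:

* :func:`simulate_confocal_photons` — freely diffusing ~100 nm proteoliposomes
  carrying zero or one two-state FRET emitter (plug open, E ~0.2, vs closed,
  E ~0.4) crossing a 3D-Gaussian confocal volume under 40 µs ALEX
  alternation, with Poisson background.  Particles re-enter the focus, so
  the stream carries genuine recurrence statistics.
* :func:`simulate_tirf_traces` — immobilised complexes imaged by msALEX TIRF
  (100 ms cyan / 100 ms orange excitation): alternating exponential closed
  dwells and gamma open dwells whose mean grows linearly with substrate
  length, truncated by single-step photobleaching.

Both retain the complete ground truth (state paths, particle identity, dwell
lists) so every downstream estimator can be verified against it.

All randomness flows from a single integer seed per call; independent
sub-streams are derived with a counter-based splitting rule so results are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bursts import ACCEPTOR, DONOR, PhotonStream

__all__ = [
    "TwoStateModel",
    "ConfocalSimConfig",
    "TirfSimConfig",
    "ConfigurationError",
    "simulate_confocal_photons",
    "simulate_tirf_traces",
    "make_atp_series",
    "make_temperature_series",
    "write_tirf_tsv",
]

OPEN, CLOSED = 1, 0


class ConfigurationError(ValueError):
    pass


def _split_rng(seed: int, *tags: int) -> np.random.Generator:
    """Counter-based seed splitting: one generator per (seed, tag...)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *tags]))


# ---------------------------------------------------------------------------
# Models and configurations
# ---------------------------------------------------------------------------

@dataclass
class TwoStateModel:
    """Two-state plug emitter: open (low E) <-> closed (high E).

    ``k_open`` is the closed->open rate, ``k_close`` the open->closed rate;
    their sum is the relaxation rate lambda of the chain.  ``brightness_ratio``
    is the ratio of mean detected count rates open/closed (epsilon).
    """

    e_open: float = 0.2
    e_closed: float = 0.4
    k_open: float = 100.0
    k_close: float = 100.0
    brightness_ratio: float = 1.0

    def __post_init__(self) -> None:
        for e in (self.e_open, self.e_closed):
            if not 0.0 <= e <= 1.0:
                raise ConfigurationError("FRET efficiencies must lie in [0, 1]")
        if self.k_open < 0 or self.k_close < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.brightness_ratio <= 0:
            raise ConfigurationError("brightness ratio must be positive")

    @property
    def rate_sum(self) -> float:
        return self.k_open + self.k_close

    @property
    def open_fraction(self) -> float:
        lam = self.rate_sum
        return self.k_open / lam if lam > 0 else 0.0


@dataclass
class ConfocalSimConfig:
    """Freely-diffusing confocal ALEX simulation parameters.

    Geometry defaults are conventional for a single-molecule confocal setup
    (0.35 µm lateral / 1.5 µm axial 1/e^2 waists); the diffusion coefficient
    default is the Stokes-Einstein value for a 100 nm vesicle in water at
    25 °C (~4.4 µm²/s).  ``concentration`` is the number of particles in the
    periodic simulation box (lateral side 10x the lateral waist).
    """

    diffusion_coefficient: float = 4.4        # µm²/s
    waist_xy: float = 0.35                    # µm
    waist_z: float = 1.5                      # µm
    concentration: float = 2.0                # particles per box
    peak_brightness: float = 150e3            # detected photons/s at focus, Dex
    acceptor_brightness: Optional[float] = None  # Aex; defaults to peak_brightness
    background_rate_donor: float = 1500.0     # photons/s
    background_rate_acceptor: float = 1500.0  # photons/s
    alternation_period_us: float = 40.0
    duty_cycle: float = 0.4
    clock_resolution: float = 12.5e-9         # s/tick
    duration: float = 10.0                    # s
    dt: float = 1e-5                          # diffusion time step, s
    box_factor: float = 14.0                  # lateral box side / waist_xy
    seed: int = 0
    initial_positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.clock_resolution <= 0 or self.dt <= 0:
            raise ConfigurationError("clock resolution and dt must be positive")
        if not 0.0 < self.duty_cycle < 1.0:
            raise ConfigurationError("duty cycle must lie in (0, 1)")
        for r in (self.peak_brightness, self.background_rate_donor,
                  self.background_rate_acceptor, self.diffusion_coefficient):
            if r < 0:
                raise ConfigurationError("rates must be non-negative")

    @property
    def box(self) -> np.ndarray:
        """Periodic box full side lengths (x, y, z) in µm."""
        side = self.box_factor * self.waist_xy
        return np.array([side, side, 4.0 * self.waist_z])


@dataclass
class TirfSimConfig:
    """msALEX TIRF trace simulation parameters.

    Open-state dwells are gamma distributed with mean ``offset_s +
    length / rate_aa_per_s`` (shape ``gamma_shape``); closed dwells are
    exponential.  Each dye photobleaches at an exponential time, truncating
    the usable trace with a single-step intensity drop.  Defaults reproduce
    the no-chaperone translocation condition: ~39.6 aa/s intrinsic rate with
    a 4.7 s length-independent offset.
    """

    lengths: Sequence[int] = (100, 233, 354, 683)   # substrate lengths, aa
    rate_aa_per_s: float = 39.6
    offset_s: float = 4.7
    closed_mean_s: float = 8.0
    gamma_shape: float = 4.0
    photobleach_mean_s: float = 60.0
    frame_period_s: float = 0.2
    excitation_period_ms: float = 100.0
    snr: float = 3.0            # FRET step amplitude / per-frame E noise SD
    total_intensity: float = 1000.0
    e_open: float = 0.2
    e_closed: float = 0.4
    n_traces: object = 200     # per substrate length (int or per-length list)
    trace_duration_s: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lengths) == 0:
            raise ConfigurationError("need at least one substrate length")
        if any(L <= 0 for L in self.lengths):
            raise ConfigurationError("substrate lengths must be positive")
        if self.rate_aa_per_s <= 0:
            raise ConfigurationError("translocation rate must be positive")
        if self.offset_s < 0:
            raise ConfigurationError("offset must be non-negative")
        if self.frame_period_s <= 0:
            raise ConfigurationError("frame period must be positive")


# ---------------------------------------------------------------------------
# Confocal photon stream simulation
# ---------------------------------------------------------------------------

def _sample_ctmc(model: TwoStateModel, duration: float, rng,
                 initial_state: Optional[int] = None):
    """Exact continuous-time Markov chain path: (switch_times, states).

    ``states[i]`` holds between ``switch_times[i]`` and ``switch_times[i+1]``.
    """
    if initial_state is None:
        if model.rate_sum == 0:
            s = CLOSED
        else:
            s = OPEN if rng.random() < model.open_fraction else CLOSED
    else:
        s = initial_state
    times, states = [0.0], [s]
    t = 0.0
    while True:
        k_out = model.k_close if s == OPEN else model.k_open
        if k_out <= 0:
            break
        t += rng.exponential(1.0 / k_out)
        if t >= duration:
            break
        s = CLOSED if s == OPEN else OPEN
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states, dtype=np.int8)


def _state_at(times: np.ndarray, switch_times: np.ndarray,
              states: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(switch_times, times, side="right") - 1
    return states[np.clip(idx, 0, len(states) - 1)]


def simulate_confocal_photons(model: TwoStateModel, cfg: ConfocalSimConfig,
                              initial_state: Optional[str] = None) -> PhotonStream:
    """Simulate an ALEX photon stream from diffusing two-state emitters.

    Each particle performs discrete-time Brownian motion in a periodic box,
    switches states as a continuous-time Markov chain and emits photons as
    an inhomogeneous Poisson process modulated by the 3D-Gaussian detection
    profile.  Emission is generated by Poisson thinning so that every photon
    timestamp is consistent with its excitation slot (timestamp modulo the
    alternation period).  During donor excitation a photon lands in the
    acceptor channel with probability equal to the current state's E; during
    acceptor excitation all signal photons are acceptor-channel photons.

    Ground truth (particle id and state per photon, full state paths) is
    retained on the returned stream; background photons carry id -1.
    """
    init = {None: None, "open": OPEN, "closed": CLOSED}[initial_state]
    rng_pos = _split_rng(cfg.seed, 0)
    rng_state = _split_rng(cfg.seed, 1)
    rng_phot = _split_rng(cfg.seed, 2)
    rng_bg = _split_rng(cfg.seed, 3)

    n_p = int(round(cfg.concentration))
    period_s = cfg.alternation_period_us * 1e-6
    donor_slot_s = cfg.duty_cycle * period_s
    box = cfg.box
    b_open, b_closed = model.brightness_ratio, 1.0
    B_A = cfg.peak_brightness if cfg.acceptor_brightness is None \
        else cfg.acceptor_brightness
    B_max = max(cfg.peak_brightness * max(b_open, b_closed), B_A, 1e-300)

    paths = []
    for p in range(n_p):
        paths.append(_sample_ctmc(model, cfg.duration, rng_state, init))

    times_list, ch_list, pid_list, st_list = [], [], [], []
    if n_p > 0 and cfg.peak_brightness > 0:
        if cfg.initial_positions is not None:
            pos = np.array(cfg.initial_positions, dtype=float).reshape(n_p, 3)
        else:
            pos = (rng_pos.uniform(-0.5, 0.5, (n_p, 3))) * box
        n_steps = int(round(cfg.duration / cfg.dt))
        step_sd = np.sqrt(2.0 * cfg.diffusion_coefficient * cfg.dt)
        chunk = 1 << 19
        for c0 in range(0, n_steps, chunk):
            c1 = min(c0 + chunk, n_steps)
            m = c1 - c0
            if step_sd > 0:
                disp = rng_pos.normal(0.0, step_sd, (n_p, m, 3))
                traj = pos[:, None, :] + np.cumsum(disp, axis=1)
            else:
                traj = np.broadcast_to(pos[:, None, :], (n_p, m, 3)).copy()
            pos = traj[:, -1, :].copy()
            # wrap into the periodic box centred on the focus
            wrapped = (traj + 0.5 * box) % box - 0.5 * box
            g = np.exp(-2.0 * ((wrapped[..., 0] ** 2 + wrapped[..., 1] ** 2)
                               / cfg.waist_xy ** 2
                               + wrapped[..., 2] ** 2 / cfg.waist_z ** 2))
            del traj, wrapped
            counts = rng_phot.poisson(B_max * g * cfg.dt)
            p_idx, s_idx = np.nonzero(counts)
            if len(p_idx) == 0:
                continue
            reps = counts[p_idx, s_idx]
            p_idx = np.repeat(p_idx, reps)
            s_idx = np.repeat(s_idx, reps)
            g_ph = np.repeat(g[np.nonzero(counts)], reps)
            t_ph = (c0 + s_idx + rng_phot.random(len(s_idx))) * cfg.dt
            # state of each photon's particle at the photon time
            st = np.empty(len(t_ph), dtype=np.int8)
            for p in range(n_p):
                sel = p_idx == p
                if np.any(sel):
                    st[sel] = _state_at(t_ph[sel], *paths[p])
            slot_dex = (t_ph % period_s) < donor_slot_s
            bright = np.where(st == OPEN, b_open, b_closed)
            rate = np.where(slot_dex, cfg.peak_brightness * bright, B_A)
            keep = rng_phot.random(len(t_ph)) * B_max < rate
            t_ph, p_idx, st, slot_dex = (t_ph[keep], p_idx[keep], st[keep],
                                         slot_dex[keep])
            e_state = np.where(st == OPEN, model.e_open, model.e_closed)
            to_acceptor = np.where(slot_dex,
                                   rng_phot.random(len(t_ph)) < e_state, True)
            times_list.append(t_ph)
            ch_list.append(np.where(to_acceptor, ACCEPTOR, DONOR).astype(np.uint8))
            pid_list.append(p_idx.astype(np.int32))
            st_list.append(st)

    # homogeneous Poisson background, per detector channel
    for ch_id, rate in ((DONOR, cfg.background_rate_donor),
                        (ACCEPTOR, cfg.background_rate_acceptor)):
        n_bg = rng_bg.poisson(rate * cfg.duration)
        t_bg = rng_bg.uniform(0.0, cfg.duration, n_bg)
        times_list.append(t_bg)
        ch_list.append(np.full(n_bg, ch_id, dtype=np.uint8))
        pid_list.append(np.full(n_bg, -1, dtype=np.int32))
        st_list.append(np.full(n_bg, -1, dtype=np.int8))

    t_all = np.concatenate(times_list) if times_list else np.empty(0)
    ch_all = np.concatenate(ch_list) if ch_list else np.empty(0, dtype=np.uint8)
    pid_all = np.concatenate(pid_list) if pid_list else np.empty(0, dtype=np.int32)
    st_all = np.concatenate(st_list) if st_list else np.empty(0, dtype=np.int8)
    order = np.argsort(t_all, kind="stable")
    ticks = np.floor(t_all[order] / cfg.clock_resolution).astype(np.int64)
    period_ticks = max(int(round(period_s / cfg.clock_resolution)), 1)
    truth = {"state_paths": paths,
             "model": model,
             "open_fraction": model.open_fraction}
    return PhotonStream(
        timestamps=ticks,
        channel=ch_all[order],
        clock_rate=1.0 / cfg.clock_resolution,
        alternation_period_ticks=period_ticks,
        duty_cycle=cfg.duty_cycle,
        particle=pid_all[order],
        state=st_all[order],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# TIRF trace simulation
# ---------------------------------------------------------------------------

def _dwell_sequence(cfg: TirfSimConfig, length: int, rng):
    """Alternating closed/open dwells covering one trace, starting closed."""
    open_mean = cfg.offset_s + length / cfg.rate_aa_per_s
    scale = open_mean / cfg.gamma_shape
    t, state = 0.0, CLOSED
    starts, states, durs = [], [], []
    while t < cfg.trace_duration_s:
        d = (rng.exponential(cfg.closed_mean_s) if state == CLOSED
             else rng.gamma(cfg.gamma_shape, scale))
        starts.append(t)
        states.append(state)
        durs.append(d)
        t += d
        state = OPEN if state == CLOSED else CLOSED
    return np.asarray(starts), np.asarray(states, dtype=np.int8), np.asarray(durs)


def simulate_tirf_traces(cfg: TirfSimConfig, forced_dwells=None):
    """Simulate msALEX TIRF intensity traces with ground-truth dwells.

    Returns ``(frames, truth)``: a frame table (trace_id, length_aa, time_s,
    I_DD, I_DA, I_AA) and a ground-truth dwell table (trace_id, length_aa,
    state 'open'/'closed', t_start_s, duration_s, censored).  A dwell is
    censored when photobleaching of either dye (or the end of the movie)
    truncates it.  Noise is EMCCD-like: Gaussian read noise plus
    scaled-Poisson shot noise, with total SD ``total_intensity / snr`` at
    full intensity; ``snr=inf`` gives noiseless traces.

    ``forced_dwells`` — list of (state, duration_s) tuples — overrides the
    stochastic dwell sequence for a single trace (construction of exact
    step-position fixtures).
    """
    rng = _split_rng(cfg.seed, 10)
    frame = cfg.frame_period_s
    noiseless = not np.isfinite(cfg.snr)
    # channel noise set so that the open/closed intensity step is snr times
    # the per-frame noise SD
    step = abs(cfg.e_closed - cfg.e_open) * cfg.total_intensity
    sigma_tot = 0.0 if noiseless else step / cfg.snr
    # split total noise variance evenly between read and shot components
    gain = sigma_tot ** 2 / (2.0 * cfg.total_intensity) if sigma_tot > 0 else 0.0
    sigma_read = sigma_tot / np.sqrt(2.0)

    frames_rows, dwell_rows, bleach_rows = [], [], []
    trace_id = 0
    jobs = []
    if forced_dwells is not None:
        jobs.append((int(cfg.lengths[0]), forced_dwells))
    else:
        try:
            per_length = [int(n) for n in cfg.n_traces]
        except TypeError:
            per_length = [int(cfg.n_traces)] * len(cfg.lengths)
        for L, n_l in zip(cfg.lengths, per_length):
            jobs.extend((int(L), None) for _ in range(n_l))

    for length, forced in jobs:
        if forced is None:
            starts, states, durs = _dwell_sequence(cfg, length, rng)
        else:
            durs = np.asarray([d for _, d in forced], dtype=float)
            states = np.asarray([OPEN if s == "open" else CLOSED
                                 for s, _ in forced], dtype=np.int8)
            starts = np.concatenate(([0.0], np.cumsum(durs)[:-1]))
        t_bleach_d = rng.exponential(cfg.photobleach_mean_s)
        t_bleach_a = rng.exponential(cfg.photobleach_mean_s)
        if forced is not None:
            t_bleach_d = t_bleach_a = np.inf
        bleach_rows.append(dict(trace_id=trace_id, length_aa=length,
                                t_bleach_donor=t_bleach_d,
                                t_bleach_acceptor=t_bleach_a))
        t_end = min(cfg.trace_duration_s, float(starts[-1] + durs[-1])) \
            if forced is not None else cfg.trace_duration_s
        n_frames = int(np.floor(t_end / frame))
        if n_frames < 1:
            continue
        edges = frame * np.arange(n_frames + 1)
        # fraction of each frame spent in the open state (exact integration
        # of the piecewise-constant state path)
        bounds = np.concatenate((starts, [starts[-1] + durs[-1]]))
        cum_open = np.concatenate(
            ([0.0], np.cumsum(np.where(states == OPEN, durs, 0.0))))
        idx = np.clip(np.searchsorted(bounds, edges, side="right") - 1,
                      0, len(durs) - 1)
        c_at_edges = cum_open[idx] + np.where(
            states[idx] == OPEN, edges - bounds[idx], 0.0)
        f_open = np.diff(np.clip(c_at_edges, 0.0, None)) / frame
        e_frame = f_open * cfg.e_open + (1.0 - f_open) * cfg.e_closed
        I = cfg.total_intensity
        i_dd = I * (1.0 - e_frame)
        i_da = I * e_frame
        i_aa = np.full(n_frames, I)
        mids = edges[:-1] + 0.5 * frame
        donor_alive = mids < t_bleach_d
        acceptor_alive = mids < t_bleach_a
        # acceptor bleach: FRET lost, full donor signal recovered
        i_da = np.where(acceptor_alive, i_da, 0.0)
        i_aa = np.where(acceptor_alive, i_aa, 0.0)
        i_dd = np.where(acceptor_alive, i_dd, I)
        # donor bleach: donor-excited signal lost entirely
        i_dd = np.where(donor_alive, i_dd, 0.0)
        i_da = np.where(donor_alive & acceptor_alive, i_da, 0.0)
        if not noiseless:
            def noisy(x):
                shot = gain * rng.poisson(np.maximum(x, 0.0) / gain) \
                    if gain > 0 else x
                return shot + rng.normal(0.0, sigma_read, n_frames)
            i_dd, i_da, i_aa = noisy(i_dd), noisy(i_da), noisy(i_aa)
        frames_rows.append(pd.DataFrame({
            "trace_id": trace_id, "length_aa": length,
            "time_s": mids, "I_DD": i_dd, "I_DA": i_da, "I_AA": i_aa,
        }))
        t_usable = min(t_bleach_d, t_bleach_a, t_end)
        for s0, st, d in zip(starts, states, durs):
            if s0 >= t_usable:
                break
            censored = s0 + d > t_usable
            dwell_rows.append(dict(
                trace_id=trace_id, length_aa=length,
                state="open" if st == OPEN else "closed",
                t_start_s=s0,
                duration_s=(min(s0 + d, t_usable) - s0) if censored else d,
                censored=censored,
            ))
        trace_id += 1

    frames = (pd.concat(frames_rows, ignore_index=True) if frames_rows
              else pd.DataFrame(columns=["trace_id", "length_aa", "time_s",
                                         "I_DD", "I_DA", "I_AA"]))
    truth = pd.DataFrame(dwell_rows, columns=["trace_id", "length_aa", "state",
                                              "t_start_s", "duration_s",
                                              "censored"])
    truth.attrs["bleach"] = pd.DataFrame(bleach_rows)
    return frames, truth


def write_tirf_tsv(frames: pd.DataFrame, path, truth: Optional[pd.DataFrame] = None,
                   truth_path=None) -> None:
    frames.to_csv(path, sep="\t", index=False)
    if truth is not None and truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ATP and temperature series
# ---------------------------------------------------------------------------

def make_atp_series(tau_min: float, K: float, atp_grid: Sequence[float],
                    noise: float = 0.1, n: int = 50, seed: int = 0) -> pd.DataFrame:
    """Opening time constants vs ATP: tau(S) = tau_min * (1 + K/S).

    ``noise`` is the coefficient of variation of the replicate scatter.
    Returns a table with one row per replicate (atp, tau_s).
    """
    if tau_min <= 0 or K <= 0:
        raise ConfigurationError("tau_min and K must be positive")
    atp = np.asarray(atp_grid, dtype=float)
    if atp.size == 0 or np.any(atp <= 0):
        raise ConfigurationError("ATP concentrations must be positive")
    rng = _split_rng(seed, 20)
    rows = []
    for s in atp:
        tau = tau_min * (1.0 + K / s)
        vals = tau * (1.0 + noise * rng.standard_normal(n))
        rows.append(pd.DataFrame({"atp": s, "tau_s": np.abs(vals)}))
    return pd.concat(rows, ignore_index=True)


def make_temperature_series(lnA: float, ea_slope: float,
                            temp_grid: Sequence[float], noise: float = 0.05,
                            n: int = 20, seed: int = 0) -> pd.DataFrame:
    """Rate constants vs temperature: ln k = lnA + ea_slope / T.

    ``ea_slope`` is in kelvin and equals -Ea/R.  ``noise`` is the CV of the
    replicate scatter on k.
    """
    temps = np.asarray(temp_grid, dtype=float)
    if temps.size == 0:
        raise ConfigurationError("temperature grid must be non-empty")
    if np.any(temps <= 0):
        raise ConfigurationError("temperatures must be positive (kelvin)")
    rng = _split_rng(seed, 21)
    rows = []
    for T in temps:
        k = np.exp(lnA + ea_slope / T)
        vals = k * (1.0 + noise * rng.standard_normal(n))
        rows.append(pd.DataFrame({"temperature_K": T, "k_per_s": np.abs(vals)}))
    return pd.concat(rows, ignore_index=True)
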