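"""Recurrence analysis of single particles (RASP).

At picomolar dilution a burst detected shortly after a previous one most
likely originates from the *same* particle re-entering the confocal volume.
Selecting second bursts by the recurrence interval T after initial bursts
with E in a chosen window dE1 turns a free-diffusion experiment into a
time-resolved kinetics measurement on the 0.1–100 ms scale.

The same-molecule probability is estimated from the burst-time
autocorrelation, P_same(tau) = 1 - 1/g(tau).  For a two-state system the
fraction of second bursts in state A relaxes as

    pA(tau) = P_same(tau) * pA_recur(tau) + (1 - P_same(tau)) * pA_new
    pA_recur = (1 + eps * (1/rhoA - 1))^-1
    rhoA(tau) = rhoA_eq + (rhoA(0) - rhoA_eq) * exp(-lambda * tau)

where lambda is the sum of the forward and backward rate constants and eps
the open/closed brightness ratio.  Fitting pA across a series of recurrence
intervals yields lambda and the equilibrium occupancy, hence the opening and
closing time constants.

The module also provides the hyperbolic ATP-dependence fit
tau(S) = tau_min * (1 + K/S) and the Arrhenius fit for activation energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bursts import BurstSet, ParameterError

__all__ = [
    "SameMoleculeCurve",
    "RecurrenceSet",
    "KineticFit",
    "burst_autocorrelation",
    "select_recurrence_pairs",
    "recurrence_histogram",
    "transition_density_2d",
    "fit_recurrence_kinetics",
    "log_intervals",
    "fit_atp_dependence",
    "fit_arrhenius",
    "GAS_CONSTANT",
]

GAS_CONSTANT = 8.314  # J / (mol K)


def _burst_times_e(bursts) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (start, stop, E) per burst.

    Recurrence times are measured from the *end* of the initial burst to the
    start of the second one: that is the interval during which the molecule
    is unobserved and free to interconvert, and it is the clock on which
    recurrence trains from a single focal transit produce sub-millisecond
    pairs.  Tuple input (times, E) is treated as point-like bursts
    (stop = start).
    """
    if isinstance(bursts, BurstSet):
        df = bursts.df
        t = df["t_start_s"].to_numpy(float)
        t_stop = df["t_stop_s"].to_numpy(float) if "t_stop_s" in df else t
        e = df["E_corr"].to_numpy(float) if "E_corr" in df else df["PR"].to_numpy(float)
        return t, t_stop, e
    if len(bursts) == 3:
        t, t_stop, e = bursts
        return (np.asarray(t, float), np.asarray(t_stop, float),
                np.asarray(e, float))
    t, e = bursts
    t = np.asarray(t, float)
    return t, t, np.asarray(e, float)


# ---------------------------------------------------------------------------
# Same-molecule probability
# ---------------------------------------------------------------------------

@dataclass
class SameMoleculeCurve:
    tau: np.ndarray       # bin centres, s
    g: np.ndarray         # burst-time autocorrelation, 1 for Poisson bursts
    p_same: np.ndarray    # 1 - 1/g, clipped to [0, 1)
    smooth_halfwidth_s: float = 5e-3   # local-averaging window for lookups

    def g_smooth(self, tau) -> np.ndarray:
        """Locally averaged autocorrelation: mean of the binned g estimate
        within +-smooth_halfwidth_s of each requested lag (individual 1 ms
        bins are Poisson-noisy at high dilution)."""
        tau = np.atleast_1d(np.asarray(tau, dtype=float))
        out = np.empty(len(tau))
        for i, x in enumerate(tau):
            m = np.abs(self.tau - x) <= self.smooth_halfwidth_s
            out[i] = np.mean(self.g[m]) if m.any() else np.interp(
                x, self.tau, self.g)
        return out

    def p_same_at(self, tau) -> np.ndarray:
        """P_same from the locally averaged autocorrelation."""
        g = np.maximum(self.g_smooth(tau), 1e-12)
        res = np.clip(1.0 - 1.0 / g, 0.0, 1.0 - 1e-9)
        return res if res.size > 1 else float(res[0])


def burst_autocorrelation(bursts, tau_max: float = 0.1,
                          bin_width: float = 1e-3) -> SameMoleculeCurve:
    """Burst-start-time autocorrelation g(tau) and P_same = 1 - 1/g.

    g is estimated by direct pair counting in bins of ``bin_width``,
    normalised by the pair count expected for a Poisson process with the
    same mean burst rate, so uncorrelated bursts give g = 1.
    """
    t, t_stop, _ = _burst_times_e(bursts)
    if len(t) < 2:
        raise ParameterError("need at least two bursts")
    order = np.argsort(t, kind="stable")
    t, t_stop = t[order], t_stop[order]
    T = t[-1] - t[0]
    if tau_max >= T:
        warnings.warn("tau grid exceeds record length; truncating")
        tau_max = T / 2
    edges = np.arange(0.0, tau_max + bin_width, bin_width)
    n = len(t)
    counts = np.empty(len(edges) - 1)
    hi_prev = np.searchsorted(t, t_stop + edges[0], side="right")
    for k in range(1, len(edges)):
        hi = np.searchsorted(t, t_stop + edges[k], side="right")
        counts[k - 1] = np.sum(hi - hi_prev)
        hi_prev = hi
    rate = n / T
    expected = n * rate * bin_width
    g = counts / expected
    with np.errstate(divide="ignore"):
        p_same = np.clip(1.0 - 1.0 / np.maximum(g, 1e-12), 0.0, 1.0 - 1e-9)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return SameMoleculeCurve(tau=centres, g=g, p_same=p_same)


# ---------------------------------------------------------------------------
# Recurrence pair selection and histograms
# ---------------------------------------------------------------------------

@dataclass
class RecurrenceSet:
    """Burst pairs {b1, b2} with E(b1) in dE1 and t(b2) - t(b1) in T."""

    e1_range: Tuple[float, float]
    interval: Tuple[float, float]
    i1: np.ndarray        # indices of initial bursts
    i2: np.ndarray        # indices of second bursts
    tau: np.ndarray       # pair recurrence (gap) times, s
    tau_eff: np.ndarray   # midpoint-to-midpoint times, s (kinetic clock)
    e1: np.ndarray
    e2: np.ndarray

    def __len__(self) -> int:
        return len(self.i1)


def select_recurrence_pairs(bursts, e1_range: Tuple[float, float],
                            interval: Tuple[float, float]) -> RecurrenceSet:
    """Exact selection R(dE1, T): all ordered burst pairs whose initial
    burst has E within ``e1_range`` (closed) and whose recurrence time —
    start of b2 minus end of b1 — lies in the interval (t1, t2]."""
    t, t_stop, e = _burst_times_e(bursts)
    order = np.argsort(t, kind="stable")
    t, t_stop, e = t[order], t_stop[order], e[order]
    t1, t2 = interval
    if t1 > t2:
        raise ParameterError("recurrence interval must have t1 <= t2")
    lo, hi = e1_range
    sel = np.flatnonzero((e >= lo) & (e <= hi))
    i1_list, i2_list = [], []
    left = np.searchsorted(t, t_stop[sel] + t1, side="right")
    right = np.searchsorted(t, t_stop[sel] + t2, side="right")
    for s, a, b in zip(sel, left, right):
        if b > a:
            i2 = np.arange(a, b)
            i1_list.append(np.full(len(i2), s))
            i2_list.append(i2)
    if i1_list:
        i1 = np.concatenate(i1_list)
        i2 = np.concatenate(i2_list)
    else:
        i1 = i2 = np.empty(0, dtype=int)
    if len(i1):
        tau = t[i2] - t_stop[i1]
        # state evolution continues during the bursts themselves: the
        # kinetic clock runs between the two E measurements, approximated
        # by the burst midpoints
        tau_eff = tau + 0.5 * ((t_stop[i1] - t[i1]) + (t_stop[i2] - t[i2]))
    else:
        tau = tau_eff = np.empty(0)
    return RecurrenceSet(e1_range=e1_range, interval=interval,
                         i1=order[i1] if len(i1) else i1,
                         i2=order[i2] if len(i2) else i2,
                         tau=tau, tau_eff=tau_eff,
                         e1=e[i1] if len(i1) else np.empty(0),
                         e2=e[i2] if len(i2) else np.empty(0))


def recurrence_histogram(rset: RecurrenceSet, bins=50):
    """Density-normalised recurrence transfer-efficiency histogram of E(b2)."""
    if len(rset) == 0:
        warnings.warn("empty recurrence set")
    hist, edges = np.histogram(rset.e2, bins=bins, range=(0.0, 1.0),
                               density=len(rset) > 0)
    return hist, edges


def transition_density_2d(bursts, interval: Tuple[float, float],
                          grid: int = 101, bandwidth: Optional[float] = None):
    """2D Gaussian KDE of burst pairs (E1, E2) for one recurrence interval.

    Returns (axis, density) with density evaluated on a grid over [0,1]^2 —
    the transition-density plot; off-diagonal mass reveals interconversion
    within the interval.
    """
    if bandwidth is not None and bandwidth <= 0:
        raise ParameterError("bandwidth must be positive")
    rset = select_recurrence_pairs(bursts, (0.0, 1.0), interval)
    axis = np.linspace(0.0, 1.0, grid)
    if len(rset) < 3:
        warnings.warn("too few pairs for a KDE; returning zeros")
        return axis, np.zeros((grid, grid))
    pts = np.vstack((rset.e1, rset.e2))
    try:
        kde = stats.gaussian_kde(pts, bw_method=bandwidth)
    except np.linalg.LinAlgError:
        # degenerate pair sets (collinear / repeated points) get a small
        # jitter so a finite-bandwidth density still comes out
        jitter = 1e-3 * np.random.default_rng(0).standard_normal(pts.shape)
        kde = stats.gaussian_kde(pts + jitter, bw_method=bandwidth)
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    dens = kde(np.vstack((xx.ravel(), yy.ravel()))).reshape(grid, grid)
    return axis, dens


def off_diagonal_fraction(axis: np.ndarray, density: np.ndarray,
                          width: float = 0.1) -> float:
    """Fraction of KDE mass farther than ``width`` from the E1=E2 diagonal."""
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    off = np.abs(xx - yy) > width
    tot = density.sum()
    return float(density[off].sum() / tot) if tot > 0 else 0.0


# ---------------------------------------------------------------------------
# Kinetic recurrence fit
# ---------------------------------------------------------------------------

@dataclass
class TwoGaussianPeaks:
    """Fixed peak model for states A (low E, open) and B (high E, closed)."""
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


@dataclass
class KineticFit:
    lam: float                    # sum of interconversion rates, 1/s
    rho_a_eq: float               # equilibrium probability of state A (open)
    rho_a0: float                 # initial conditional probability
    p_a_new: float                # P(state A) for newly arriving molecules
    eps: float
    tau_open_s: float             # 1 / (lambda * rho_a_eq)
    tau_close_s: float            # 1 / (lambda * (1 - rho_a_eq))
    intervals: pd.DataFrame = field(repr=False)
    ci: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def p_a_recurrent(rho_a, eps: float = 1.0):
    """Probability that a recurring molecule's burst is assigned to state A,
    given occupancy rho_a and brightness ratio eps.  Identity map at eps=1."""
    rho_a = np.asarray(rho_a, dtype=float)
    with np.errstate(divide="ignore"):
        return 1.0 / (1.0 + eps * (1.0 / np.maximum(rho_a, 1e-300) - 1.0))


def _peak_fractions(e2: np.ndarray, peaks: TwoGaussianPeaks, edges: np.ndarray):
    """Fraction of histogram area in peak A from a two-peak decomposition
    with fixed means/widths (non-negative least squares on the histogram)."""
    hist, _ = np.histogram(e2, bins=edges, density=True)
    centres = 0.5 * (edges[:-1] + edges[1:])
    ga = stats.norm.pdf(centres, peaks.mean_a, peaks.sd_a)
    gb = stats.norm.pdf(centres, peaks.mean_b, peaks.sd_b)
    A = np.column_stack((ga, gb))
    w, _ = optimize.nnls(A, hist)
    tot = w.sum()
    return (w[0] / tot) if tot > 0 else np.nan


def default_peaks(e_open: float = 0.2, e_closed: float = 0.4,
                  n_photons: Optional[int] = None,
                  sd: float = 0.07) -> TwoGaussianPeaks:
    """Two-Gaussian peak model at the state E values.

    When ``n_photons`` is given the widths are set to the binomial shot
    noise of an n-photon proximity-ratio estimate, added in quadrature to a
    small intrinsic width.
    """
    if n_photons is not None:
        sd_a = float(np.hypot(sd / 2, np.sqrt(e_open * (1 - e_open) / n_photons)))
        sd_b = float(np.hypot(sd / 2, np.sqrt(e_closed * (1 - e_closed) / n_photons)))
        return TwoGaussianPeaks(mean_a=e_open, sd_a=sd_a,
                                mean_b=e_closed, sd_b=sd_b)
    return TwoGaussianPeaks(mean_a=e_open, sd_a=sd, mean_b=e_closed, sd_b=sd)


def log_intervals(t_lo: float = 5e-4, t_hi: float = 0.08,
                  n: int = 8) -> list:
    """n logarithmically spaced recurrence intervals between t_lo and t_hi."""
    edges = np.geomspace(t_lo, t_hi, n + 1)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def segment_estimates(bursts: "BurstSet", n_photons: int = 30,
                      background=None):
    """Per-burst head/tail proximity-ratio estimates.

    Burst-averaged E blurs kinetics when bursts last as long as the
    relaxation time: the state keeps evolving while the molecule is in
    focus.  The tail estimate (last ``n_photons`` donor-excitation photons)
    reports the state when the molecule *leaves* the volume; the head
    estimate (first ``n_photons``) the state when it *returns*.  Using the
    tail of b1 for the initial-E selection and the head of b2 for the
    recurrence histogram puts the kinetic clock on the gap between the two
    measurements.  Falls back to None when the burst set carries no photon
    -level data.  When a background estimate is supplied the expected
    background counts over each window's time span are subtracted from the
    window's channel counts (windows at burst edges carry the largest
    background fraction, which otherwise pulls both peaks towards the
    background proximity ratio of ~0.5).
    """
    from .bursts import ACCEPTOR, DEX

    stream = bursts.stream
    if stream is None:
        return None
    t_ph = stream.times_s
    n = len(bursts.df)
    e_head = np.full(n, np.nan)
    e_tail = np.full(n, np.nan)
    t_head = np.full(n, np.nan)
    t_tail = np.full(n, np.nan)

    def window_pr(widx):
        n_a = float(np.sum(stream.channel[widx] == ACCEPTOR))
        n_tot = float(len(widx))
        if background is not None and len(widx) > 1:
            span = t_ph[widx[-1]] - t_ph[widx[0]]
            mid = 0.5 * (t_ph[widx[0]] + t_ph[widx[-1]])
            n_a -= float(background.rate_at(mid, "da")) * span
            n_tot -= float(background.rate_at(mid, "da")
                           + background.rate_at(mid, "dd")) * span
        if n_tot <= 0:
            return np.nan
        return float(np.clip(n_a / n_tot, 0.0, 1.0))

    for b, row in enumerate(bursts.df.itertuples()):
        idx = np.arange(int(row.i_start), int(row.i_stop))
        dex = stream.excitation[idx] == DEX
        didx = idx[dex]
        if len(didx) == 0:
            continue
        head = didx[:n_photons]
        tail = didx[-n_photons:]
        e_head[b] = window_pr(head)
        e_tail[b] = window_pr(tail)
        t_head[b] = float(np.mean(t_ph[head]))
        t_tail[b] = float(np.mean(t_ph[tail]))
    return {"e_head": e_head, "e_tail": e_tail,
            "t_head": t_head, "t_tail": t_tail}


def fit_recurrence_kinetics(bursts, e1_range: Tuple[float, float],
                            intervals: Sequence[Tuple[float, float]],
                            p_same: SameMoleculeCurve,
                            peaks: Optional[TwoGaussianPeaks] = None,
                            eps: float = 1.0,
                            p_a_new: Optional[float] = None,
                            e1_range2: object = "auto",
                            fix_rho_eq: bool = True,
                            segment_photons: Optional[int] = 30,
                            background=None,
                            hist_bins: int = 50,
                            n_boot: int = 200,
                            seed: int = 0) -> KineticFit:
    """Global two-state kinetic fit to a recurrence-interval series.

    For every interval the recurrence histogram of E(b2) is decomposed into
    the two fixed peaks (shared means/widths, free weights) giving the
    state-A fraction pA(tau); the relaxation model is then fit globally with
    free (lambda, rhoA_eq, rhoA(0)).  The new-molecule probability pA_new is
    determined from the globally fitted peak areas of the full burst
    histogram unless supplied explicitly.  Peak A is the low-E (open) state.

    When the burst set carries photon-level data, the initial-E selection
    uses the tail segment of b1 and the histogram the head segment of b2
    (see :func:`segment_estimates`); otherwise burst-averaged E is used with
    a midpoint-to-midpoint clock.

    By detailed balance the complementary selection on the other state's
    peak carries independent information about the same lambda; by default
    (``e1_range2="auto"``) the mirror window on peak B is fit jointly,
    sharing lambda and the equilibrium, with its own initial probability.
    Uncertainties are percentile bootstrap over bursts.
    """
    if len(intervals) < 4:
        raise ParameterError("need at least four recurrence intervals")
    if peaks is None:
        peaks = default_peaks(n_photons=segment_photons)
    t, t_stop, e = _burst_times_e(bursts)
    seg = None
    if segment_photons is not None and isinstance(bursts, BurstSet):
        seg = segment_estimates(bursts, segment_photons, background=background)
    if seg is not None:
        e_sel, e_meas = seg["e_tail"], seg["e_head"]
        tm1 = np.where(np.isfinite(seg["t_tail"]), seg["t_tail"], t_stop)
        tm2 = np.where(np.isfinite(seg["t_head"]), seg["t_head"], t)
    else:
        e_sel = e_meas = e
        tm1 = 0.5 * (t + t_stop)
        tm2 = tm1
    edges = np.linspace(0.0, 1.0, hist_bins + 1)
    if p_a_new is None:
        p_a_new = float(_peak_fractions(e_meas[np.isfinite(e_meas)], peaks, edges))

    order0 = np.argsort(t, kind="stable")
    data0 = tuple(a[order0] for a in (t, t_stop, e_sel, e_meas, tm1, tm2))

    if e1_range2 == "auto":
        mid = 0.5 * (peaks.mean_a + peaks.mean_b)
        e1_range2 = (mid + (mid - e1_range[1]), mid + (mid - e1_range[0]))
    windows = [tuple(e1_range)]
    if e1_range2 is not None:
        windows.append(tuple(e1_range2))

    def measure_window(window, tt, tt_stop, esel, emeas, m1, m2):
        lo_e, hi_e = window
        # forward selection: E(tail of b1) in the window, histogram head of b2;
        # the time-reversed selection (head of the later burst in the window,
        # histogram tail of the earlier) is statistically equivalent at
        # equilibrium (detailed balance) and doubles the pair count
        sel_f = np.flatnonzero((esel >= lo_e) & (esel <= hi_e))
        sel_r = np.flatnonzero((emeas >= lo_e) & (emeas <= hi_e))
        taus, pas, ns = [], [], []
        for t1, t2 in intervals:
            e2_parts, tau_parts = [], []
            left = np.searchsorted(tt, tt_stop[sel_f] + t1, side="right")
            right = np.searchsorted(tt, tt_stop[sel_f] + t2, side="right")
            for s, a, b in zip(sel_f, left, right):
                if b > a:
                    i2 = np.arange(a, b)
                    e2_parts.append(emeas[i2])
                    tau_parts.append(m2[i2] - m1[s])
            left = np.searchsorted(tt_stop, tt[sel_r] - t2, side="left")
            right = np.searchsorted(tt_stop, tt[sel_r] - t1, side="left")
            for s, a, b in zip(sel_r, left, right):
                if b > a:
                    i1 = np.arange(a, b)
                    e2_parts.append(esel[i1])
                    tau_parts.append(m2[s] - m1[i1])
            if not e2_parts:
                taus.append(np.nan); pas.append(np.nan); ns.append(0)
                continue
            e2 = np.concatenate(e2_parts)
            tau_eff = np.concatenate(tau_parts)
            okp = np.isfinite(e2) & np.isfinite(tau_eff)
            if okp.sum() < 10:
                taus.append(np.nan); pas.append(np.nan); ns.append(int(okp.sum()))
                continue
            taus.append(float(np.mean(tau_eff[okp])))
            pas.append(_peak_fractions(e2[okp], peaks, edges))
            ns.append(int(okp.sum()))
        return np.asarray(taus), np.asarray(pas), np.asarray(ns)

    def measure(*data):
        return [measure_window(wdw, *data) for wdw in windows]

    def fit_once(series):
        # a recurring molecule at tau -> infinity carries the equilibrium
        # state marginal -- the same marginal the global peak areas (pA_new)
        # decompose -- so the plateau may be tied to pA_new, reducing the
        # free-parameter count (fix_rho_eq)
        usable = []
        for taus, pas, ns in series:
            ok = np.isfinite(taus) & np.isfinite(pas)
            usable.append((taus[ok], pas[ok], np.sqrt(ns[ok]),
                           p_same.p_same_at(taus[ok])))
        n_ok = sum(len(u[0]) for u in usable)
        if len(usable[0][0]) < (3 if fix_rho_eq else 4):
            return None
        n_w = len(usable)

        def unpack(theta):
            if fix_rho_eq:
                lam = theta[0]
                rho_eq = p_a_new
                rho0s = theta[1:1 + n_w]
            else:
                lam, rho_eq = theta[0], theta[1]
                rho0s = theta[2:2 + n_w]
            return lam, rho_eq, rho0s

        def resid(theta):
            lam, rho_eq, rho0s = unpack(theta)
            out = []
            for (taus_f, pas_f, w, ps), rho0 in zip(usable, rho0s):
                rho = rho_eq + (rho0 - rho_eq) * np.exp(-lam * taus_f)
                model = ps * p_a_recurrent(rho, eps) + (1.0 - ps) * p_a_new
                out.append(w * (model - pas_f))
            return np.concatenate(out)

        best, best_cost = None, np.inf
        rho0_guess = [np.clip(u[1][0], 0.05, 0.95) if len(u[1]) else 0.5
                      for u in usable]
        for lam0 in (20.0, 100.0, 400.0):
            if fix_rho_eq:
                x0 = np.array([lam0, *rho0_guess])
                bounds = ([0.0] * (1 + n_w), [1e4] + [1.0] * n_w)
            else:
                x0 = np.array([lam0, 0.5, *rho0_guess])
                bounds = ([0.0] * (2 + n_w), [1e4] + [1.0] * (1 + n_w))
            try:
                res = optimize.least_squares(resid, x0, bounds=bounds)
            except Exception:
                continue
            if res.cost < best_cost:
                best, best_cost = res, res.cost
        if best is None:
            return None
        lam, rho_eq, rho0s = unpack(best.x)
        return np.array([lam, rho_eq, rho0s[0]])

    series0 = measure(*data0)
    theta = fit_once(series0)
    flags = []
    if theta is None:
        raise RuntimeError("recurrence kinetic fit failed: too few usable intervals")
    lam, rho_eq, rho0 = theta
    taus, pas, ns = series0[0]
    if lam > 0 and np.nanmax(taus) < 1.0 / lam:
        flags.append("unidentifiable: intervals shorter than 1/lambda")

    rng = np.random.default_rng(seed)
    boot = []
    n_bursts = len(t)
    stacked = np.column_stack((t, t_stop, e_sel, e_meas, tm1, tm2))
    for _ in range(n_boot):
        idx = rng.integers(0, n_bursts, n_bursts)
        sub = stacked[idx]
        sub = sub[np.argsort(sub[:, 0], kind="stable")]
        th = fit_once(measure(*(sub[:, j] for j in range(6))))
        if th is not None:
            boot.append(th)
    ci = {}
    if boot:
        boot = np.asarray(boot)
        lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
        names = ("lam", "rho_a_eq", "rho_a0")
        ci = {k: (float(a), float(b)) for k, a, b in zip(names, lo, hi)}
        with np.errstate(divide="ignore"):
            tau_close_b = 1.0 / (boot[:, 0] * (1.0 - boot[:, 1]))
            tau_open_b = 1.0 / (boot[:, 0] * boot[:, 1])
        ci["tau_close_s"] = tuple(np.percentile(
            tau_close_b[np.isfinite(tau_close_b)], [2.5, 97.5]))
        ci["tau_open_s"] = tuple(np.percentile(
            tau_open_b[np.isfinite(tau_open_b)], [2.5, 97.5]))

    tables = []
    for wdw, (taus_w, pas_w, ns_w) in zip(windows, series0):
        tables.append(pd.DataFrame({
            "window_lo": wdw[0], "window_hi": wdw[1],
            "t_lo": [iv[0] for iv in intervals],
            "t_hi": [iv[1] for iv in intervals],
            "tau_mean_s": taus_w, "p_a": pas_w, "n_pairs": ns_w,
        }))
    interval_table = pd.concat(tables, ignore_index=True)
    k_open = lam * rho_eq         # rate into A (opening)
    k_close = lam * (1.0 - rho_eq)
    return KineticFit(
        lam=float(lam), rho_a_eq=float(rho_eq), rho_a0=float(rho0),
        p_a_new=float(p_a_new), eps=eps,
        tau_open_s=float(1.0 / k_open) if k_open > 0 else np.inf,
        tau_close_s=float(1.0 / k_close) if k_close > 0 else np.inf,
        intervals=interval_table, ci=ci, flags=flags,
    )


# ---------------------------------------------------------------------------
# ATP dependence and Arrhenius fits
# ---------------------------------------------------------------------------

@dataclass
class AtpFit:
    tau_min: float
    K: float
    tau_min_se: float
    K_se: float
    ci95_K: Tuple[float, float]


def fit_atp_dependence(table: pd.DataFrame, atp_col: str = "atp",
                       tau_col: str = "tau_s") -> AtpFit:
    """Weighted least-squares fit of tau(S) = tau_min * (1 + K/S).

    Replicates are aggregated per ATP level; levels are weighted by the
    standard error of their mean.
    """
    if np.any(table[atp_col] <= 0):
        raise ValueError("ATP concentrations must be positive")
    grp = table.groupby(atp_col)[tau_col]
    s = grp.mean().index.to_numpy(float)
    if len(s) < 3:
        raise ValueError("need at least three ATP levels")
    y = grp.mean().to_numpy(float)
    n = grp.count().to_numpy(float)
    sd = grp.std(ddof=1).to_numpy(float)
    sigma = np.where(np.isfinite(sd) & (sd > 0), sd / np.sqrt(n), np.nanmax(y) * 1e-3)

    def model(sconc, tau_min, K):
        return tau_min * (1.0 + K / sconc)

    p0 = (float(y.min()), float(s[np.argmin(np.abs(y - 2 * y.min()))]))
    popt, pcov = optimize.curve_fit(model, s, y, p0=p0, sigma=sigma,
                                    absolute_sigma=False, maxfev=10000)
    perr = np.sqrt(np.diag(pcov))
    dof = max(len(s) - 2, 1)
    tcrit = stats.t.ppf(0.975, dof)
    return AtpFit(tau_min=float(popt[0]), K=float(popt[1]),
                  tau_min_se=float(perr[0]), K_se=float(perr[1]),
                  ci95_K=(float(popt[1] - tcrit * perr[1]),
                          float(popt[1] + tcrit * perr[1])))


@dataclass
class ArrheniusFit:
    Ea_J_per_mol: float
    Ea_se: float
    lnA: float
    lnA_se: float
    ci95_Ea: Tuple[float, float]

    @property
    def Ea_kJ_per_mol(self) -> float:
        return self.Ea_J_per_mol / 1e3


def fit_arrhenius(table: pd.DataFrame, temp_col: str = "temperature_K",
                  k_col: str = "k_per_s") -> ArrheniusFit:
    """Arrhenius fit: ln k vs 1/T, Ea = -slope * R."""
    T = table[temp_col].to_numpy(float)
    k = table[k_col].to_numpy(float)
    if np.any(k <= 0):
        raise ValueError("rate constants must be positive")
    if len(np.unique(T)) < 2:
        raise ValueError("need at least two distinct temperatures")
    res = stats.linregress(1.0 / T, np.log(k))
    Ea = -res.slope * GAS_CONSTANT
    Ea_se = res.stderr * GAS_CONSTANT
    dof = max(len(T) - 2, 1)
    tcrit = stats.t.ppf(0.975, dof)
    return ArrheniusFit(Ea_J_per_mol=float(Ea), Ea_se=float(Ea_se),
                        lnA=float(res.intercept),
                        lnA_se=float(res.intercept_stderr),
                        ci95_Ea=(float(Ea - tcrit * Ea_se),
                                 float(Ea + tcrit * Ea_se)))
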