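"""Burst variance analysis (BVA).

Detects within-burst dynamics by comparing the empirical standard deviation
of sub-burst proximity ratios against the binomial shot-noise expectation

    S_Esub = sqrt(E_p (1 - E_p) / n)

for sub-bursts of n donor-excitation photons.  Upper-tail confidence
thresholds are obtained by Monte Carlo: for every proximity-ratio bin the
observed window structure (M_i windows for each burst i) is replayed with
binomial draws F_Aij ~ B(n, PR_i), the pooled deviation statistic is
aggregated over the bin, and the (1 - alpha) quantile of the resulting
distribution is the static expectation's ceiling.

BVA operates on the *proximity ratio* only: detected photons partition
between the two channels binomially with success probability PR, so the
shot-noise reference is exact for PR but biased for corrected FRET
efficiencies.  All entry points therefore work from raw per-photon channel
sequences, never from corrected E values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .bursts import ACCEPTOR, DEX, BurstSet, ParameterError

__all__ = [
    "BVAConfig",
    "BVAResult",
    "SubBurstPartition",
    "subdivide_bursts",
    "subdivide_bursts_time",
    "burst_sd",
    "shot_noise_sd",
    "mc_confidence",
    "classify_dynamics",
]


@dataclass
class BVAConfig:
    n_photons: int = 5          # donor-excitation photons per sub-burst
    n_bins: int = 20            # proximity-ratio bins over [0, 1]
    alpha: float = 0.001        # per-bin upper-tail confidence level
    n_replicates: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_photons < 2:
            raise ParameterError("sub-burst photon count must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")


@dataclass
class SubBurstPartition:
    """Sub-burst window structure: for each retained burst, its windows'
    acceptor counts.  Bursts with fewer than two windows are excluded."""

    n: int                       # photons per window (photon partitioner)
    burst_id: np.ndarray         # one entry per window
    f_a: np.ndarray              # acceptor counts per window
    window_n: np.ndarray         # photons per window (== n for photon mode)

    @property
    def e_p(self) -> np.ndarray:
        return self.f_a / self.window_n


def _donor_excitation_channels(bursts: BurstSet, row) -> np.ndarray:
    stream = bursts.stream
    if stream is None:
        raise ParameterError(
            "BVA needs a stream-backed BurstSet with per-photon channels")
    idx = bursts.photon_indices(row)
    ch = stream.channel[idx]
    exc = stream.excitation[idx]
    return ch[exc == DEX]


def subdivide_bursts(bursts: BurstSet, n: int = 5) -> SubBurstPartition:
    """Partition each burst's donor-excitation photons into consecutive
    windows of exactly n photons; the trailing remainder is discarded and
    bursts yielding fewer than two windows are dropped."""
    if n < 2:
        raise ParameterError("n must be >= 2")
    bids, fas = [], []
    for b, row in enumerate(bursts.df.itertuples()):
        ch = _donor_excitation_channels(bursts, row)
        n_win = len(ch) // n
        if n_win < 2:
            continue
        acc = (ch[: n_win * n] == ACCEPTOR).reshape(n_win, n).sum(axis=1)
        bids.append(np.full(n_win, b))
        fas.append(acc)
    if bids:
        burst_id = np.concatenate(bids)
        f_a = np.concatenate(fas)
    else:
        burst_id = np.empty(0, dtype=int)
        f_a = np.empty(0, dtype=int)
    return SubBurstPartition(n=n, burst_id=burst_id, f_a=f_a.astype(float),
                             window_n=np.full(len(f_a), n, dtype=float))


def subdivide_bursts_time(bursts: BurstSet, window_s: float = 1e-4,
                          min_photons: int = 2) -> SubBurstPartition:
    """Alternative partitioner: fixed *time* windows (default 0.1 ms), for
    probing dynamics on a set timescale rather than a set photon count.
    Windows with fewer than ``min_photons`` donor-excitation photons are
    dropped; E_p uses each window's own photon count."""
    if window_s <= 0:
        raise ParameterError("window must be positive")
    stream = bursts.stream
    if stream is None:
        raise ParameterError("BVA needs a stream-backed BurstSet")
    t = stream.times_s
    bids, fas, ns = [], [], []
    for b, row in enumerate(bursts.df.itertuples()):
        idx = bursts.photon_indices(row)
        dex = stream.excitation[idx] == DEX
        tt = t[idx][dex]
        ch = stream.channel[idx][dex]
        if len(tt) == 0:
            continue
        w = np.floor((tt - tt[0]) / window_s).astype(int)
        acc = np.bincount(w, weights=(ch == ACCEPTOR))
        tot = np.bincount(w)
        keep = tot >= min_photons
        if keep.sum() < 2:
            continue
        bids.append(np.full(keep.sum(), b))
        fas.append(acc[keep])
        ns.append(tot[keep])
    if bids:
        return SubBurstPartition(n=0, burst_id=np.concatenate(bids),
                                 f_a=np.concatenate(fas).astype(float),
                                 window_n=np.concatenate(ns).astype(float))
    return SubBurstPartition(n=0, burst_id=np.empty(0, dtype=int),
                             f_a=np.empty(0), window_n=np.empty(0))


def burst_sd(partition: SubBurstPartition) -> pd.DataFrame:
    """Per-burst mean proximity ratio and empirical sub-burst SD.

    The SD uses the population denominator (N), matching the Monte Carlo
    reference statistic.
    """
    ep = partition.e_p
    df = pd.DataFrame({"burst_id": partition.burst_id, "e_p": ep})
    out = df.groupby("burst_id")["e_p"].agg(
        mean_e_p="mean", s_e=lambda x: float(np.std(x, ddof=0)),
        n_windows="count").reset_index()
    return out


def shot_noise_sd(e_p, n):
    """Binomial shot-noise SD of the sub-burst proximity ratio."""
    e_p = np.asarray(e_p, dtype=float)
    if np.any((e_p < 0) | (e_p > 1)):
        raise ParameterError("E_p must lie in [0, 1]")
    return np.sqrt(e_p * (1.0 - e_p) / n)


def _pooled_stat(f_a: np.ndarray, window_n: np.ndarray) -> float:
    """Pooled SD of window proximity ratios about the pooled mean."""
    pr = f_a / window_n
    mu = pr.mean()
    return float(np.sqrt(np.mean((pr - mu) ** 2)))


@dataclass
class BVAResult:
    per_burst: pd.DataFrame      # burst_id, mean_e_p, s_e, n_windows
    per_bin: pd.DataFrame        # bin edges, mean s_E, threshold, verdict
    config: BVAConfig

    @property
    def any_dynamic(self) -> bool:
        return bool(self.per_bin["dynamic"].any())


def mc_confidence(partition: SubBurstPartition, cfg: Optional[BVAConfig] = None,
                  per_burst: Optional[pd.DataFrame] = None) -> BVAResult:
    """Monte Carlo confidence thresholds per proximity-ratio bin.

    For each bin [L, U) over burst mean E_p, replicate the bin's exact
    window structure with binomial draws (n trials, success PR_i per burst),
    aggregate the pooled deviation statistic, and take the (1 - alpha)
    quantile of the Monte Carlo distribution as the shot-noise ceiling.
    """
    cfg = cfg or BVAConfig()
    rng = np.random.default_rng(cfg.seed)
    if per_burst is None:
        per_burst = burst_sd(partition)
    edges = np.linspace(0.0, 1.0, cfg.n_bins + 1)
    rows = []
    for k in range(cfg.n_bins):
        lo, hi = edges[k], edges[k + 1]
        last = k == cfg.n_bins - 1
        in_bin = (per_burst["mean_e_p"] >= lo) & (
            (per_burst["mean_e_p"] <= hi) if last else (per_burst["mean_e_p"] < hi))
        sel = per_burst[in_bin]
        if len(sel) == 0:
            rows.append(dict(e_lo=lo, e_hi=hi, n_bursts=0, mean_s_e=np.nan,
                             threshold=np.nan, dynamic=False, no_verdict=True))
            continue
        wmask = np.isin(partition.burst_id, sel["burst_id"].to_numpy())
        w_n = partition.window_n[wmask]
        pr_burst = sel.set_index("burst_id")["mean_e_p"]
        pr_w = pr_burst.loc[partition.burst_id[wmask]].to_numpy(float)
        observed = _pooled_stat(partition.f_a[wmask], w_n)
        draws = rng.binomial(np.tile(w_n.astype(int), (cfg.n_replicates, 1)),
                             np.tile(pr_w, (cfg.n_replicates, 1)))
        pr_sim = draws / w_n
        mu = pr_sim.mean(axis=1, keepdims=True)
        stat = np.sqrt(np.mean((pr_sim - mu) ** 2, axis=1))
        thr = float(np.quantile(stat, 1.0 - cfg.alpha))
        rows.append(dict(e_lo=lo, e_hi=hi, n_bursts=int(len(sel)),
                         mean_s_e=observed, threshold=thr,
                         dynamic=bool(observed > thr), no_verdict=False))
    per_bin = pd.DataFrame(rows)
    if per_bin["no_verdict"].all():
        warnings.warn("no bin contained bursts; no BVA verdicts")
    return BVAResult(per_burst=per_burst, per_bin=per_bin, config=cfg)


def classify_dynamics(result: BVAResult) -> pd.DataFrame:
    """Plot-ready per-bin verdict table (E_p bin, mean s_E, shot-noise SD,
    MC threshold, static/dynamic verdict)."""
    tab = result.per_bin.copy()
    centre = 0.5 * (tab["e_lo"] + tab["e_hi"])
    n_ref = result.config.n_photons if result.config.n_photons >= 2 else 2
    tab.insert(2, "e_centre", centre)
    tab["shot_noise_sd"] = shot_noise_sd(centre, n_ref)
    tab["verdict"] = np.where(tab["no_verdict"], "no data",
                              np.where(tab["dynamic"], "dynamic", "static"))
    return tab
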