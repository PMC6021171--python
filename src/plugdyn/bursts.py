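"""Confocal µsALEX burst analysis core.

Photon-stream container and HDF5 I/O, time-resolved background estimation,
dual-channel burst search (DCBS) in sliding-window mode, burst-wise FRET
efficiency / stoichiometry with population-level corrections, and
stoichiometry filtering.

Conventions
-----------
Detector channels: 0 = donor, 1 = acceptor.  Excitation slots: 0 = donor
excitation (Dex), 1 = acceptor excitation (Aex).  A photon's slot is
derivable from its timestamp modulo the laser alternation period: the first
``duty_cycle`` fraction of each period is donor excitation.

Count nomenclature follows the ALEX literature: ``n_DD`` donor-excitation
donor-channel counts, ``n_DA`` donor-excitation acceptor-channel counts
(FRET-sensitized), ``n_AA`` acceptor-excitation acceptor-channel counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "PhotonStream",
    "BackgroundEstimate",
    "BurstSet",
    "CorrectionFactors",
    "FormatError",
    "DataError",
    "ParameterError",
    "read_photon_stream",
    "write_photon_stream",
    "estimate_background",
    "search_bursts_dcbs",
    "compute_burst_es",
    "filter_bursts",
    "corrected_efficiency",
]

DONOR, ACCEPTOR = 0, 1
DEX, AEX = 0, 1


class FormatError(ValueError):
    """File does not carry the metadata required to interpret it."""


class DataError(ValueError):
    """Input data violate a structural invariant (e.g. unsorted timestamps)."""


class ParameterError(ValueError):
    """Analysis parameter outside its valid range."""


# ---------------------------------------------------------------------------
# Photon stream
# ---------------------------------------------------------------------------

@dataclass
class PhotonStream:
    """Timestamped, channel- and excitation-resolved photon record.

    Parameters
    ----------
    timestamps : int64 array, clock ticks, monotone non-decreasing
    channel : uint8 array, 0 donor / 1 acceptor detector
    clock_rate : ticks per second
    alternation_period_ticks : ALEX period in ticks (None if unknown)
    duty_cycle : donor-excitation fraction of the period
    excitation : uint8 array, 0 Dex / 1 Aex; recomputed from the alternation
        metadata when not supplied
    particle, state : optional ground-truth labels carried by simulated
        streams (-1 marks background photons)
    """

    timestamps: np.ndarray
    channel: np.ndarray
    clock_rate: float
    alternation_period_ticks: Optional[int] = None
    duty_cycle: float = 0.4
    excitation: Optional[np.ndarray] = None
    particle: Optional[np.ndarray] = None
    state: Optional[np.ndarray] = None
    truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.channel = np.asarray(self.channel, dtype=np.uint8)
        if self.timestamps.shape != self.channel.shape:
            raise DataError("timestamps and channel must have equal length")
        if np.any(np.diff(self.timestamps) < 0):
            raise DataError("photon timestamps must be sorted")
        if self.excitation is None:
            if self.alternation_period_ticks is None:
                raise FormatError(
                    "need either per-photon excitation labels or alternation metadata"
                )
            self.excitation = self.compute_excitation(self.timestamps)
        else:
            self.excitation = np.asarray(self.excitation, dtype=np.uint8)

    def compute_excitation(self, ticks: np.ndarray) -> np.ndarray:
        period = self.alternation_period_ticks
        phase = np.asarray(ticks, dtype=np.int64) % period
        return np.where(phase < self.duty_cycle * period, DEX, AEX).astype(np.uint8)

    @property
    def times_s(self) -> np.ndarray:
        return self.timestamps / self.clock_rate

    @property
    def duration_s(self) -> float:
        if len(self.timestamps) == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0]) / self.clock_rate

    def __len__(self) -> int:
        return len(self.timestamps)


def write_photon_stream(stream: PhotonStream, path) -> None:
    """Write a stream to a photon-HDF5-style layout.

    Timestamps are stored as integer ticks under ``/photon_data`` with the
    clock rate and alternation metadata as group attributes.
    """
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=stream.timestamps, dtype=np.int64)
        g.create_dataset("detectors", data=stream.channel, dtype=np.uint8)
        g.create_dataset("excitation", data=stream.excitation, dtype=np.uint8)
        if stream.particle is not None:
            g.create_dataset("particle", data=stream.particle, dtype=np.int32)
        if stream.state is not None:
            g.create_dataset("state", data=stream.state, dtype=np.int8)
        g.attrs["clock_rate"] = stream.clock_rate
        g.attrs["duty_cycle"] = stream.duty_cycle
        if stream.alternation_period_ticks is not None:
            g.attrs["alternation_period_ticks"] = stream.alternation_period_ticks


def read_photon_stream(path) -> PhotonStream:
    """Read a photon-HDF5-style file written by :func:`write_photon_stream`.

    Excitation slots are recomputed from the alternation metadata when the
    per-photon dataset is absent; a file carrying neither is rejected.
    """
    with h5py.File(path, "r") as f:
        if "photon_data" not in f:
            raise FormatError("missing /photon_data group")
        g = f["photon_data"]
        if "clock_rate" not in g.attrs:
            raise FormatError("missing clock_rate metadata")
        ts = g["timestamps"][()]
        if np.any(np.diff(ts) < 0):
            raise DataError("unsorted timestamps on disk")
        exc = g["excitation"][()] if "excitation" in g else None
        period = g.attrs.get("alternation_period_ticks")
        if exc is None and period is None:
            raise FormatError("no excitation labels and no alternation metadata")
        return PhotonStream(
            timestamps=ts,
            channel=g["detectors"][()],
            clock_rate=float(g.attrs["clock_rate"]),
            alternation_period_ticks=None if period is None else int(period),
            duty_cycle=float(g.attrs.get("duty_cycle", 0.4)),
            excitation=exc,
            particle=g["particle"][()] if "particle" in g else None,
            state=g["state"][()] if "state" in g else None,
        )


# ---------------------------------------------------------------------------
# Background estimation
# ---------------------------------------------------------------------------

#: photon sub-streams used throughout the analysis
_STREAM_KEYS = ("dex_total", "aex_acceptor", "dd", "da", "aa")


def _substream_mask(stream: PhotonStream, key: str) -> np.ndarray:
    ch, exc = stream.channel, stream.excitation
    if key == "dex_total":
        return exc == DEX
    if key == "aex_acceptor":
        return (exc == AEX) & (ch == ACCEPTOR)
    if key == "dd":
        return (exc == DEX) & (ch == DONOR)
    if key == "da":
        return (exc == DEX) & (ch == ACCEPTOR)
    if key == "aa":
        return (exc == AEX) & (ch == ACCEPTOR)
    raise KeyError(key)


@dataclass
class BackgroundEstimate:
    """Piecewise-constant background rates per photon sub-stream.

    ``rates[key]`` holds one rate (photons/s) per window of ``edges``.
    Windows with too few delays inherit their neighbour's rate and are
    flagged in ``carried_over``.
    """

    edges: np.ndarray           # window boundaries, seconds
    rates: dict                 # key -> array of len(edges) - 1
    window_s: float
    carried_over: dict          # key -> boolean array

    def rate_at(self, t_s, key: str) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.edges, t_s, side="right") - 1,
                      0, len(self.edges) - 2)
        return self.rates[key][idx]

    def mean_rate(self, key: str) -> float:
        return float(np.mean(self.rates[key]))


def _mle_rate_from_delays(delays: np.ndarray, min_delays: int = 20):
    """Poisson background rate from the exponential tail of photon delays.

    Burst photons produce anomalously short delays; the fit therefore keeps
    only delays above a threshold and exploits the memorylessness of the
    exponential law: ``E[d - thr | d > thr] = 1/rate``.  The threshold is set
    to twice the current mean-delay estimate and refined once.
    """
    if len(delays) < min_delays:
        return None
    rate = 1.0 / float(np.mean(delays))
    for _ in range(2):
        thr = 2.0 / rate
        tail = delays[delays >= thr]
        if len(tail) < min_delays:
            break
        rate = 1.0 / (float(np.mean(tail)) - thr)
    return rate


def estimate_background(stream: PhotonStream, window_s: float = 10.0,
                        min_delays: int = 20) -> BackgroundEstimate:
    """Estimate per-stream background rates as a function of time.

    Maximum-likelihood exponential fit to inter-photon delays in consecutive
    windows of ``window_s`` seconds, separately for each channel×excitation
    sub-stream.
    """
    if len(stream) == 0:
        raise DataError("cannot estimate background of an empty stream")
    t = stream.times_s
    t0, t1 = float(t[0]), float(t[-1])
    if window_s >= max(t1 - t0, 1e-12) and t1 - t0 > 0:
        window_s = t1 - t0
    n_win = max(1, int(np.ceil((t1 - t0) / window_s)))
    edges = t0 + window_s * np.arange(n_win + 1)
    rates, flags = {}, {}
    for key in _STREAM_KEYS:
        tk = t[_substream_mask(stream, key)]
        r = np.full(n_win, np.nan)
        for w in range(n_win):
            seg = tk[(tk >= edges[w]) & (tk < edges[w + 1])]
            est = _mle_rate_from_delays(np.diff(seg), min_delays)
            if est is not None:
                r[w] = est
        flag = np.isnan(r)
        if np.all(flag):
            # fall back to the global naive rate for this sub-stream
            r[:] = max(len(tk), 1) / max(t1 - t0, window_s)
        else:
            # carry rates over from the nearest estimated window
            good = np.flatnonzero(~flag)
            r = r[good[np.argmin(np.abs(np.arange(n_win)[:, None] - good[None, :]),
                                 axis=1)]]
        rates[key], flags[key] = r, flag
    return BackgroundEstimate(edges=edges, rates=rates, window_s=window_s,
                              carried_over=flags)


# ---------------------------------------------------------------------------
# Burst search
# ---------------------------------------------------------------------------

@dataclass
class CorrectionFactors:
    """Population-level E correction factors.

    leakage : donor emission detected in the acceptor channel (fraction)
    direct_excitation : acceptor excitation by the donor laser (fraction)
    gamma : detection-efficiency / quantum-yield ratio
    """

    leakage: float = 0.0
    direct_excitation: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.leakage < 0 or self.direct_excitation < 0:
            raise ParameterError("leakage and direct excitation must be >= 0")
        if self.gamma <= 0:
            raise ParameterError("gamma must be positive")


def corrected_efficiency(n_dd, n_da, n_aa, corr: CorrectionFactors):
    """Accurate FRET efficiency from ALEX counts.

    E = (n_DA - l n_DD - d n_AA) / (gamma n_DD + n_DA - l n_DD - d n_AA)
    """
    n_dd = np.asarray(n_dd, dtype=float)
    n_da = np.asarray(n_da, dtype=float)
    n_aa = np.asarray(n_aa, dtype=float)
    num = n_da - corr.leakage * n_dd - corr.direct_excitation * n_aa
    den = corr.gamma * n_dd + num
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


@dataclass
class BurstSet:
    """Bursts found in one photon stream.

    ``df`` has one row per burst; ``stream`` is kept so that photon-level
    analyses (BVA) can recover each burst's photon sequence from the
    ``i_start``/``i_stop`` index range (half-open).
    """

    df: pd.DataFrame
    stream: Optional[PhotonStream] = None

    def __len__(self) -> int:
        return len(self.df)

    def photon_indices(self, row) -> np.ndarray:
        return np.arange(int(row.i_start), int(row.i_stop))

    def to_tsv(self, path) -> None:
        cols = ["burst_id", "t_start_s", "duration_ms", "n_DD", "n_DA", "n_AA"]
        for extra in ("PR", "E_corr", "S"):
            if extra in self.df.columns:
                cols.append(extra)
        out = self.df.reset_index(drop=True)
        out["burst_id"] = np.arange(len(out))
        out["duration_ms"] = out["duration_s"] * 1e3
        out[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BurstSet":
        df = pd.read_csv(path, sep="\t")
        df["duration_s"] = df["duration_ms"] * 1e-3
        return cls(df=df, stream=None)


def _hot_intervals(t: np.ndarray, bg_rate_at, m: int, F: float):
    """Time intervals where the local m-photon rate exceeds F x background.

    Sliding-window mode: the criterion is evaluated at every photon.  A
    photon is 'hot' when covered by at least one qualifying window of m
    consecutive photons; runs of hot photons become intervals.
    """
    n = len(t)
    if n < m:
        return np.empty((0, 2))
    width = t[m - 1:] - t[:n - m + 1]
    # local rate m/width > F * bg  <=>  width < m / (F * bg)
    ok = width < m / (F * np.maximum(bg_rate_at(t[: n - m + 1]), 1e-300))
    hot = np.zeros(n, dtype=bool)
    starts = np.flatnonzero(ok)
    if len(starts) == 0:
        return np.empty((0, 2))
    # mark coverage [i, i+m) for each qualifying window via difference array
    diff = np.zeros(n + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + m, -1)
    hot = np.cumsum(diff[:-1]) > 0
    # runs of hot photons -> [t_first, t_last] intervals
    idx = np.flatnonzero(hot)
    gaps = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[gaps + 1]))
    run_stops = np.concatenate((idx[gaps], [idx[-1]]))
    return np.column_stack((t[run_starts], t[run_stops]))


def _intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out).reshape(-1, 2)


def search_bursts_dcbs(stream: PhotonStream, background: BackgroundEstimate,
                       m: int = 10, F: float = 6.0,
                       sliding: bool = True) -> BurstSet:
    """Background-dependent dual-channel burst search.

    A burst requires the local photon rate over ``m`` consecutive photons to
    exceed ``F`` times the local background rate simultaneously in the
    donor-excitation stream (all channels) and in the acceptor-excitation
    acceptor stream, which suppresses donor-only / acceptor-only artefacts
    and blinking.  Burst counts are split by channel x excitation slot and
    background-corrected with the local rates.
    """
    if m < 2:
        raise ParameterError("m must be >= 2")
    if F <= 1:
        raise ParameterError("F must exceed 1")
    if not sliding:
        warnings.warn("only sliding-window mode is implemented; proceeding with it")
    t = stream.times_s
    iv_d = _hot_intervals(t[_substream_mask(stream, "dex_total")],
                          lambda x: background.rate_at(x, "dex_total"), m, F)
    iv_a = _hot_intervals(t[_substream_mask(stream, "aex_acceptor")],
                          lambda x: background.rate_at(x, "aex_acceptor"), m, F)
    iv = _intersect_intervals(iv_d, iv_a)
    rows = []
    ch, exc = stream.channel, stream.excitation
    for lo, hi in iv:
        i0 = int(np.searchsorted(t, lo, side="left"))
        i1 = int(np.searchsorted(t, hi, side="right"))
        if i1 - i0 < 2:
            continue
        c = ch[i0:i1]
        e = exc[i0:i1]
        n_dd = int(np.sum((e == DEX) & (c == DONOR)))
        n_da = int(np.sum((e == DEX) & (c == ACCEPTOR)))
        n_aa = int(np.sum((e == AEX) & (c == ACCEPTOR)))
        dur = max(hi - lo, 1.0 / stream.clock_rate)
        mid = 0.5 * (lo + hi)
        bg_dd = background.rate_at(mid, "dd") * dur
        bg_da = background.rate_at(mid, "da") * dur
        bg_aa = background.rate_at(mid, "aa") * dur
        rows.append(dict(
            i_start=i0, i_stop=i1, t_start_s=lo, t_stop_s=hi, duration_s=dur,
            n_DD=n_dd, n_DA=n_da, n_AA=n_aa,
            n_DD_corr=max(n_dd - bg_dd, 0.0),
            n_DA_corr=max(n_da - bg_da, 0.0),
            n_AA_corr=max(n_aa - bg_aa, 0.0),
            size=n_dd + n_da + n_aa,
        ))
    cols = ["i_start", "i_stop", "t_start_s", "t_stop_s", "duration_s",
            "n_DD", "n_DA", "n_AA", "n_DD_corr", "n_DA_corr", "n_AA_corr", "size"]
    df = pd.DataFrame(rows, columns=cols)
    return BurstSet(df=df, stream=stream)


# ---------------------------------------------------------------------------
# E / S and filtering
# ---------------------------------------------------------------------------

def compute_burst_es(bursts: BurstSet,
                     corrections: Optional[CorrectionFactors] = None) -> BurstSet:
    """Attach proximity ratio, stoichiometry and (optionally) corrected E.

    PR and S always come from background-corrected counts.  Corrections are
    a population-level transform of burst-summed counts — photons are never
    reweighted individually.  Bursts with no donor-excitation signal are
    flagged and get undefined E.
    """
    df = bursts.df.copy()
    dd, da, aa = (df["n_DD_corr"].to_numpy(float),
                  df["n_DA_corr"].to_numpy(float),
                  df["n_AA_corr"].to_numpy(float))
    dex = dd + da
    undefined = dex <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pr = np.clip(da / dex, 0.0, 1.0)
        s = np.clip(dex / (dex + aa), 0.0, 1.0)
    pr[undefined] = np.nan
    df["PR"] = pr
    df["S"] = s
    df["E_undefined"] = undefined
    if corrections is not None:
        e = np.clip(corrected_efficiency(dd, da, aa, corrections), 0.0, 1.0)
        e[undefined] = np.nan
        df["E_corr"] = e
    else:
        df["E_corr"] = pr
    return BurstSet(df=df, stream=bursts.stream)


def filter_bursts(bursts: BurstSet, s_min: float = 0.25, s_max: float = 0.75,
                  min_size: int = 30) -> BurstSet:
    """Keep doubly-labelled bursts: s_min <= S <= s_max (closed interval)
    and total counts >= min_size."""
    if s_min >= s_max:
        raise ParameterError("s_min must be below s_max")
    df = bursts.df
    keep = (df["S"] >= s_min) & (df["S"] <= s_max) & (df["size"] >= min_size)
    keep &= ~df.get("E_undefined", pd.Series(False, index=df.index))
    out = df[keep].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("stoichiometry/size filter removed every burst")
    return BurstSet(df=out, stream=bursts.stream)
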