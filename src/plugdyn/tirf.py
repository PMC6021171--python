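"""msALEX TIRF trace analysis.

Per-frame FRET efficiency and stoichiometry, quality control (stoichiometry
window, donor/acceptor anticorrelation, single-step photobleaching,
blinking), two-state hidden-Markov segmentation into open/closed dwells,
orientation-corrected FRET histograms, and two-Gaussian mixture fits.

Reconstituted complexes insert into liposomes in both orientations; only the
~50% facing outward can engage the ATPase motor and substrate.  Histograms
of the full population are therefore corrected by subtracting the scaled
distribution of the translocon alone (the inverted, unresponsive fraction),
and time traces that never show a decoded transition are flagged
non-responsive and excluded from state histograms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bursts import CorrectionFactors, FormatError, ParameterError, corrected_efficiency

logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

__all__ = [
    "TirfTrace",
    "TirfTraceSet",
    "StateSegmentation",
    "MixtureFit",
    "read_traces",
    "write_traces",
    "trace_es",
    "qc_traces",
    "segment_states_hmm",
    "extract_dwells",
    "correct_orientation_histogram",
    "fit_gaussian_mixture",
]

REQUIRED_COLUMNS = ("trace_id", "time_s", "I_DD", "I_DA", "I_AA")


@dataclass
class TirfTrace:
    """One immobilised molecule's frame-resolved two-colour record."""

    trace_id: int
    time_s: np.ndarray
    i_dd: np.ndarray
    i_da: np.ndarray
    i_aa: np.ndarray
    length_aa: Optional[int] = None
    e: Optional[np.ndarray] = None
    s: Optional[np.ndarray] = None
    flags: dict = field(default_factory=dict)
    bleach_frame: Optional[int] = None    # first bleach event (either dye)
    bleach_channel: Optional[str] = None  # 'donor' | 'acceptor'

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    @property
    def frame_period_s(self) -> float:
        return float(np.median(np.diff(self.time_s))) if self.n_frames > 1 else np.nan

    def prebleach(self) -> slice:
        stop = self.bleach_frame if self.bleach_frame is not None else self.n_frames
        return slice(0, stop)


class TirfTraceSet:
    """Collection of TIRF traces backed by one frame table."""

    def __init__(self, frames: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in frames.columns]
        if missing:
            raise FormatError(f"missing required column(s): {missing}")
        self.frames = frames.sort_values(["trace_id", "time_s"]).reset_index(drop=True)
        self._traces: dict = {}

    @property
    def trace_ids(self):
        return self.frames["trace_id"].unique()

    def get(self, trace_id) -> TirfTrace:
        if trace_id not in self._traces:
            sub = self.frames[self.frames["trace_id"] == trace_id]
            self._traces[trace_id] = TirfTrace(
                trace_id=trace_id,
                time_s=sub["time_s"].to_numpy(float),
                i_dd=sub["I_DD"].to_numpy(float),
                i_da=sub["I_DA"].to_numpy(float),
                i_aa=sub["I_AA"].to_numpy(float),
                length_aa=(int(sub["length_aa"].iloc[0])
                           if "length_aa" in sub.columns else None),
            )
        return self._traces[trace_id]

    def __iter__(self):
        return (self.get(tid) for tid in self.trace_ids)

    def __len__(self) -> int:
        return len(self.trace_ids)


def read_traces(path) -> TirfTraceSet:
    """Read a frame TSV (trace_id, time_s, I_DD, I_DA, I_AA[, length_aa]);
    frames are sorted by time within each trace."""
    return TirfTraceSet(pd.read_csv(path, sep="\t"))


def write_traces(traces: TirfTraceSet, path) -> None:
    traces.frames.to_csv(path, sep="\t", index=False)


def trace_es(trace: TirfTrace,
             corrections: Optional[CorrectionFactors] = None) -> TirfTrace:
    """Attach per-frame E and S (frame-wise analogues of the burst formulas).

    Frames with no donor-excitation signal get undefined E; post-bleach
    frames are undefined once a bleach frame is known.  Corrected E uses the
    same formula as the confocal analysis.
    """
    dex = trace.i_dd + trace.i_da
    with np.errstate(divide="ignore", invalid="ignore"):
        if corrections is None:
            e = trace.i_da / dex
        else:
            e = corrected_efficiency(trace.i_dd, trace.i_da, trace.i_aa, corrections)
        s = dex / (dex + trace.i_aa)
    noise = _robust_noise_sd(trace.i_dd + trace.i_da)
    invalid = dex <= max(3.0 * noise, 1e-12)
    e = np.where(invalid, np.nan, e)
    if trace.bleach_frame is not None:
        e[trace.bleach_frame:] = np.nan
    trace.e = e
    trace.s = s
    return trace


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def _robust_noise_sd(x: np.ndarray) -> float:
    """Frame noise SD from the median absolute successive difference."""
    if len(x) < 3:
        return 0.0
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _detect_steps(x: np.ndarray, min_step: float, min_seg: int = 3,
                  _depth: int = 0) -> list:
    """Recursive cumulative-sum change-point detection of intensity steps.

    Returns a list of (frame_index, step_height) with negative heights for
    downward steps.  A step is retained when its height exceeds
    ``min_step``.
    """
    n = len(x)
    if n < 2 * min_seg or _depth > 4:
        return []
    xc = np.cumsum(x - x.mean())
    k = int(np.argmax(np.abs(xc[min_seg - 1:n - min_seg])) + min_seg - 1) + 1
    step = float(np.mean(x[k:]) - np.mean(x[:k]))
    if abs(step) < min_step:
        return []
    left = _detect_steps(x[:k], min_step, min_seg, _depth + 1)
    right = [(k + i, h) for i, h in _detect_steps(x[k:], min_step, min_seg,
                                                  _depth + 1)]
    return left + [(k, step)] + right


def _candidate_transitions(e: np.ndarray) -> np.ndarray:
    """Frames where E crosses the midpoint of its range (provisional
    transition locations for the anticorrelation check)."""
    e = e[np.isfinite(e)]
    if len(e) < 4:
        return np.empty(0, dtype=int)
    mid = 0.5 * (np.nanpercentile(e, 10) + np.nanpercentile(e, 90))
    above = e > mid
    return np.flatnonzero(np.diff(above.astype(int)) != 0)


@dataclass
class QCReport:
    kept: list
    excluded: pd.DataFrame       # trace_id, reason

    def to_json(self) -> dict:
        return {"n_kept": len(self.kept),
                "exclusions": self.excluded.to_dict(orient="records")}


def qc_traces(traces: TirfTraceSet, s_window: Tuple[float, float] = (0.25, 0.75),
              anticorr_threshold: float = -0.3, step_sigma: float = 4.0,
              corrections: Optional[CorrectionFactors] = None) -> QCReport:
    """Quality-control filtering of TIRF traces.

    Keeps traces whose median pre-bleach stoichiometry lies in ``s_window``,
    whose donor/acceptor intensities anticorrelate (Pearson r of I_DD vs
    I_DA over the pre-bleach, transition-containing part of the trace below
    ``anticorr_threshold``; traces without provisional transitions pass
    trivially and are sorted out later as non-responsive), and which show at
    most one bleach step per dye.  Bleach
    steps are located by a cumulative-sum change-point statistic with a
    minimum step of ``step_sigma`` x frame noise SD; the first bleach of
    either dye truncates the usable trace and its time is recorded for the
    photobleaching correction downstream.
    """
    kept, excl = [], []
    for tr in traces:
        donor_total = tr.i_dd + tr.i_da
        steps_d = [s for s in _detect_steps(donor_total,
                                            step_sigma * max(_robust_noise_sd(donor_total), 1e-9))
                   ]
        steps_a = [s for s in _detect_steps(tr.i_aa,
                                            step_sigma * max(_robust_noise_sd(tr.i_aa), 1e-9))]
        down_d = [(k, h) for k, h in steps_d if h < 0]
        down_a = [(k, h) for k, h in steps_a if h < 0]
        # an emitter loss removes a full fluorophore's worth of signal; much
        # smaller detected down-steps are noise artefacts, not extra dyes
        if down_d:
            big = max(-h for _, h in down_d)
            down_d = [(k, h) for k, h in down_d if -h >= 0.5 * big]
        if down_a:
            big = max(-h for _, h in down_a)
            down_a = [(k, h) for k, h in down_a if -h >= 0.5 * big]
        if len(down_d) > 1 or len(down_a) > 1:
            excl.append((tr.trace_id, "multi-step bleach (multiple emitters)"))
            continue
        up_d = [(k, h) for k, h in steps_d if h > 0]
        # an upward donor step without acceptor involvement suggests blinking
        tr.flags["blinking"] = bool(up_d) and not down_a
        bleach_events = []
        if down_d:
            bleach_events.append((down_d[0][0], "donor"))
        if down_a:
            # acceptor bleach raises donor signal; the paired donor up-step
            # is expected, not a second emitter
            bleach_events.append((down_a[0][0], "acceptor"))
        if bleach_events:
            k, chan = min(bleach_events)
            tr.bleach_frame, tr.bleach_channel = int(k), chan
        trace_es(tr, corrections)
        pre = tr.prebleach()
        s_med = float(np.nanmedian(tr.s[pre]))
        if not (s_window[0] <= s_med <= s_window[1]):
            excl.append((tr.trace_id, f"stoichiometry {s_med:.2f} outside window"))
            continue
        trans = _candidate_transitions(tr.e[pre])
        if len(trans) > 0 and pre.stop >= 8:
            r = float(np.corrcoef(tr.i_dd[pre], tr.i_da[pre])[0, 1])
            tr.flags["anticorr_r"] = r
            if not np.isfinite(r) or r > anticorr_threshold:
                excl.append((tr.trace_id,
                             f"donor/acceptor not anticorrelated (r={r:.2f})"))
                continue
        tr.flags["stoichiometry_pass"] = True
        kept.append(tr)
    return QCReport(kept=kept,
                    excluded=pd.DataFrame(excl, columns=["trace_id", "reason"]))


# ---------------------------------------------------------------------------
# Two-state segmentation
# ---------------------------------------------------------------------------

@dataclass
class StateSegmentation:
    trace_id: int
    labels: np.ndarray            # per pre-bleach frame: 'open' | 'closed'
    transitions: np.ndarray       # frame indices where the state changes
    dwells: pd.DataFrame          # state, t_start_s, duration_s, censored
    responsive: bool
    skipped: bool = False


def segment_states_hmm(trace: TirfTrace, n_states: int = 2,
                       means_init: Sequence[float] = (0.2, 0.4),
                       min_frames: int = 10) -> StateSegmentation:
    """Two-state Gaussian-emission HMM segmentation of a trace's E signal.

    The model is fit per trace with means initialised at the open/closed E
    values; the most probable (Viterbi) state path is decoded and collapsed
    into an alternating dwell list.  The lower-mean state is 'open'.  The
    terminal dwell (truncated by bleaching or the movie end) is censored.
    Traces with zero decoded transitions are flagged non-responsive.
    """
    from hmmlearn.hmm import GaussianHMM

    if trace.e is None:
        trace_es(trace)
    pre = trace.prebleach()
    e = trace.e[pre]
    ok = np.isfinite(e)
    if ok.sum() < min_frames:
        return StateSegmentation(trace.trace_id, np.empty(0, dtype="<U6"),
                                 np.empty(0, dtype=int),
                                 _empty_dwells(), responsive=False, skipped=True)
    x = e[ok].reshape(-1, 1)
    hmm = GaussianHMM(n_components=n_states, covariance_type="diag",
                      n_iter=100, tol=1e-4, init_params="c",
                      params="stmc", random_state=0)
    hmm.startprob_ = np.full(n_states, 1.0 / n_states)
    hmm.transmat_ = np.full((n_states, n_states), 0.05 / (n_states - 1))
    np.fill_diagonal(hmm.transmat_, 0.95)
    hmm.means_ = np.asarray(means_init, dtype=float).reshape(-1, 1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hmm.fit(x)
            path = hmm.predict(x)
    except Exception:
        # degenerate trace (e.g. constant E): threshold fallback
        mid = 0.5 * (means_init[0] + means_init[1])
        path = (x.ravel() > mid).astype(int)
        hmm_means = np.asarray(means_init)
        order = np.argsort(hmm_means)
    else:
        order = np.argsort(hmm.means_.ravel())
    rank = np.empty_like(order)
    rank[order] = np.arange(n_states)
    path = rank[path]                       # 0 = lowest mean = open
    labels_ok = np.where(path == 0, "open", "closed")
    labels = np.full(len(e), "", dtype="<U6")
    labels[ok] = labels_ok
    # fill undefined frames with the neighbouring state
    for i in range(1, len(labels)):
        if labels[i] == "":
            labels[i] = labels[i - 1]
    for i in range(len(labels) - 2, -1, -1):
        if labels[i] == "":
            labels[i] = labels[i + 1]
    transitions = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    dwells = _labels_to_dwells(trace, labels)
    return StateSegmentation(trace.trace_id, labels, transitions, dwells,
                             responsive=len(transitions) > 0)


def _empty_dwells() -> pd.DataFrame:
    return pd.DataFrame(columns=["trace_id", "state", "t_start_s",
                                 "duration_s", "censored"])


def _labels_to_dwells(trace: TirfTrace, labels: np.ndarray) -> pd.DataFrame:
    if len(labels) == 0:
        return _empty_dwells()
    frame = trace.frame_period_s
    t0 = trace.time_s[0] - 0.5 * frame
    bounds = np.concatenate(([0], np.flatnonzero(labels[1:] != labels[:-1]) + 1,
                             [len(labels)]))
    rows = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        rows.append(dict(trace_id=trace.trace_id, state=labels[a],
                         t_start_s=t0 + a * frame,
                         duration_s=(b - a) * frame,
                         censored=(b == len(labels))))
    df = pd.DataFrame(rows)
    if trace.length_aa is not None:
        df["length_aa"] = trace.length_aa
    return df


def extract_dwells(segmentations: Sequence[StateSegmentation],
                   responsive_only: bool = True) -> pd.DataFrame:
    """Pool dwell lists; by default only responsive traces contribute."""
    frames = [s.dwells for s in segmentations
              if (s.responsive or not responsive_only) and not s.skipped]
    if not frames:
        return _empty_dwells()
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

def correct_orientation_histogram(active_hist: np.ndarray,
                                  reference_hist: np.ndarray,
                                  edges: np.ndarray,
                                  inverted_fraction: float = 0.5) -> np.ndarray:
    """Remove the inverted (unresponsive) population from a FRET histogram.

    corrected = (mixture - f * reference) / (1 - f), clipped at zero and
    renormalised to unit density.  Both inputs must be density-normalised on
    the same bin grid.
    """
    if inverted_fraction >= 1.0 or inverted_fraction < 0.0:
        raise ParameterError("inverted fraction must lie in [0, 1)")
    mix = np.asarray(active_hist, dtype=float)
    ref = np.asarray(reference_hist, dtype=float)
    if mix.shape != ref.shape:
        raise ParameterError("histograms must share one bin grid")
    f = inverted_fraction
    raw = (mix - f * ref) / (1.0 - f)
    widths = np.diff(edges)
    neg_mass = float(np.sum(np.clip(-raw, 0.0, None) * widths))
    if neg_mass > 0.10:
        warnings.warn(f"negative mass {neg_mass:.2f} before clipping — "
                      "reference scaling may not describe the mixture")
    out = np.clip(raw, 0.0, None)
    total = float(np.sum(out * widths))
    return out / total if total > 0 else out


@dataclass
class MixtureFit:
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    overlapping: bool = False

    def pdf(self, x: np.ndarray) -> np.ndarray:
        from scipy.stats import norm
        x = np.asarray(x, dtype=float)
        return sum(w * norm.pdf(x, m, s) for w, m, s in
                   zip(self.weights, self.means, self.sds))


def fit_gaussian_mixture(e_values=None, hist=None, edges=None, k: int = 2,
                         bin_width: float = 0.02,
                         sd_floor: float = 0.005) -> MixtureFit:
    """Weighted least-squares two-Gaussian fit on a binned E density.

    Accepts either raw E samples (binned at ``bin_width``) or a pre-binned
    density histogram.  Components are ordered by ascending mean; degenerate
    components are refit with an SD floor; strongly overlapping components
    are flagged.
    """
    from scipy import optimize

    if hist is None:
        e = np.asarray(e_values, dtype=float)
        e = e[np.isfinite(e)]
        if len(e) < 50:
            raise ParameterError("need at least 50 observations")
        edges = np.arange(0.0, 1.0 + bin_width, bin_width)
        hist, _ = np.histogram(e, bins=edges, density=True)
        q = np.percentile(e, np.linspace(10, 90, k))
    else:
        hist = np.asarray(hist, dtype=float)
        edges = np.asarray(edges, dtype=float)
        centres_tmp = 0.5 * (edges[:-1] + edges[1:])
        cdf = np.cumsum(hist)
        cdf = cdf / cdf[-1]
        q = np.interp(np.linspace(0.1, 0.9, k), cdf, centres_tmp)
    centres = 0.5 * (edges[:-1] + edges[1:])

    def model(x, *theta):
        out = np.zeros_like(x)
        for j in range(k):
            w, m, s = theta[3 * j: 3 * j + 3]
            out = out + w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        return out

    p0 = []
    for j in range(k):
        p0 += [1.0 / k, float(q[j]), 0.05]
    lb = [0.0, 0.0, sd_floor] * k
    ub = [np.inf, 1.0, 0.5] * k
    popt, _ = optimize.curve_fit(model, centres, hist, p0=p0,
                                 bounds=(lb, ub), maxfev=20000)
    w = popt[0::3]
    m = popt[1::3]
    s = np.maximum(popt[2::3], sd_floor)
    order = np.argsort(m)
    w, m, s = w[order], m[order], s[order]
    w = w / w.sum()
    overlapping = bool(np.any(np.diff(m) < 0.5 * (s[:-1] + s[1:])))
    return MixtureFit(means=m, sds=s, weights=w, overlapping=overlapping)
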