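"""TIRF trace E/S, quality control, segmentation and histogram operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plugdyn.bursts import CorrectionFactors, FormatError, ParameterError
from plugdyn.synthetic import TirfSimConfig, simulate_tirf_traces
from plugdyn.tirf import (
    TirfTrace,
    TirfTraceSet,
    correct_orientation_histogram,
    extract_dwells,
    fit_gaussian_mixture,
    qc_traces,
    read_traces,
    segment_states_hmm,
    trace_es,
    write_traces,
)


def _trace(i_dd, i_da, i_aa, frame=0.2, trace_id=0):
    n = len(i_dd)
    return TirfTrace(trace_id=trace_id,
                     time_s=frame * (np.arange(n) + 0.5),
                     i_dd=np.asarray(i_dd, dtype=float),
                     i_da=np.asarray(i_da, dtype=float),
                     i_aa=np.asarray(i_aa, dtype=float))


def _two_state_trace(n_frames=120, period=20, noise=15.0, seed=0, i_tot=1000.0):
    """Alternating open/closed square wave in E with Gaussian noise."""
    rng = np.random.default_rng(seed)
    state = (np.arange(n_frames) // period) % 2      # 0 open, 1 closed
    e = np.where(state == 0, 0.2, 0.4)
    i_dd = i_tot * (1 - e) + rng.normal(0, noise, n_frames)
    i_da = i_tot * e + rng.normal(0, noise, n_frames)
    i_aa = np.full(n_frames, i_tot) + rng.normal(0, noise, n_frames)
    return _trace(i_dd, i_da, i_aa)


class TestIO:
    def test_round_trip(self, tirf_frames, tmp_path):
        frames, _ = tirf_frames
        ts = TirfTraceSet(frames)
        p = tmp_path / "t.tsv"
        write_traces(ts, p)
        back = read_traces(p)
        pd.testing.assert_frame_equal(back.frames, ts.frames)

    def test_shuffled_frames_sorted_on_read(self, tmp_path):
        df = pd.DataFrame({"trace_id": [0, 0, 0], "time_s": [0.5, 0.1, 0.3],
                           "I_DD": [1.0, 2.0, 3.0], "I_DA": [0, 0, 0],
                           "I_AA": [1, 1, 1]})
        p = tmp_path / "s.tsv"
        df.to_csv(p, sep="\t", index=False)
        back = read_traces(p)
        assert back.frames["time_s"].is_monotonic_increasing

    def test_missing_column_rejected(self, tmp_path):
        df = pd.DataFrame({"trace_id": [0], "time_s": [0.1], "I_DD": [1.0]})
        p = tmp_path / "bad.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(FormatError):
            read_traces(p)


class TestTraceES:
    def test_frame_arithmetic(self):
        tr = trace_es(_trace([100], [100], [200]))
        assert tr.e[0] == pytest.approx(0.5)
        assert tr.s[0] == pytest.approx(0.5)

    def test_post_bleach_frames_undefined(self):
        tr = _trace([500] * 5 + [0] * 5, [500] * 5 + [0] * 5, [1000] * 10)
        tr.bleach_frame = 5
        tr = trace_es(tr)
        assert np.all(np.isnan(tr.e[5:]))
        assert np.all(np.isfinite(tr.e[:5]))

    def test_identity_corrections_equal_raw(self):
        tr1 = trace_es(_trace([600], [400], [1000]))
        tr2 = trace_es(_trace([600], [400], [1000]),
                       CorrectionFactors(0.0, 0.0, 1.0))
        assert tr1.e[0] == pytest.approx(tr2.e[0])


class TestQC:
    def test_single_dye_stoichiometry_excluded(self):
        rng = np.random.default_rng(1)
        n = 60
        tr = _trace(1000 + rng.normal(0, 10, n), rng.normal(0, 10, n),
                    rng.normal(0, 10, n))     # S ~ 1, donor-only
        frames = pd.DataFrame({"trace_id": 0, "time_s": tr.time_s,
                               "I_DD": tr.i_dd, "I_DA": tr.i_da,
                               "I_AA": tr.i_aa})
        rep = qc_traces(TirfTraceSet(frames))
        assert len(rep.kept) == 0
        assert "stoichiometry" in rep.excluded["reason"].iloc[0]

    def test_anticorrelated_two_state_trace_retained(self):
        tr = _two_state_trace(seed=2)
        frames = pd.DataFrame({"trace_id": 0, "time_s": tr.time_s,
                               "I_DD": tr.i_dd, "I_DA": tr.i_da,
                               "I_AA": tr.i_aa})
        rep = qc_traces(TirfTraceSet(frames))
        assert len(rep.kept) == 1
        assert rep.kept[0].flags["anticorr_r"] < -0.3

    def test_two_step_donor_drop_excluded(self):
        # two emitters bleaching sequentially: two comparable down-steps
        rng = np.random.default_rng(3)
        n = 90
        i_dd = np.concatenate((np.full(30, 2000.0), np.full(30, 1000.0),
                               np.full(30, 0.0))) + rng.normal(0, 10, n)
        i_da = np.zeros(n) + rng.normal(0, 10, n)
        i_aa = np.full(n, 2000.0) + rng.normal(0, 10, n)
        frames = pd.DataFrame({"trace_id": 0,
                               "time_s": 0.2 * (np.arange(n) + 0.5),
                               "I_DD": i_dd, "I_DA": i_da, "I_AA": i_aa})
        rep = qc_traces(TirfTraceSet(frames))
        assert len(rep.kept) == 0
        assert "multi-step" in rep.excluded["reason"].iloc[0]


class TestSegmentation:
    def test_noiseless_alternating_trace_exact_dwells(self):
        tr = trace_es(_two_state_trace(noise=0.0))
        seg = segment_states_hmm(tr)
        assert seg.responsive
        d = seg.dwells
        # 20-frame square wave at 0.2 s -> 4 s dwells, alternating states
        inner = d.iloc[1:-1]
        assert np.allclose(inner["duration_s"], 4.0)
        states = d["state"].tolist()
        assert all(a != b for a, b in zip(states, states[1:]))

    def test_terminal_dwell_censored_and_tiling(self):
        tr = trace_es(_two_state_trace(seed=5))
        seg = segment_states_hmm(tr)
        d = seg.dwells
        assert bool(d["censored"].iloc[-1])
        assert not d["censored"].iloc[:-1].any()
        total = d["duration_s"].sum()
        assert total == pytest.approx(tr.n_frames * 0.2, rel=1e-6)

    def test_constant_trace_non_responsive(self):
        rng = np.random.default_rng(6)
        n = 80
        tr = trace_es(_trace(800 + rng.normal(0, 5, n),
                             200 + rng.normal(0, 5, n),
                             np.full(n, 1000.0)))
        seg = segment_states_hmm(tr)
        assert not seg.responsive
        assert extract_dwells([seg]).empty

    def test_short_trace_skipped(self):
        tr = trace_es(_trace([800] * 4, [200] * 4, [1000] * 4))
        seg = segment_states_hmm(tr)
        assert seg.skipped

    def test_noisy_traces_recover_open_dwell_mean(self):
        """Open dwells from segmented noisy traces within 10 % of truth."""
        cfg = TirfSimConfig(lengths=(100,), snr=3.0, n_traces=60,
                            photobleach_mean_s=1e6, offset_s=0.5,
                            rate_aa_per_s=40.0, seed=12)
        frames, truth = simulate_tirf_traces(cfg)
        segs = [segment_states_hmm(tr)
                for tr in qc_traces(TirfTraceSet(frames)).kept]
        d = extract_dwells(segs)
        got = d[(d.state == "open") & (~d.censored)]["duration_s"].mean()
        ref = truth[(truth.state == "open")
                    & (~truth.censored)]["duration_s"].mean()
        assert abs(got - ref) / ref < 0.10


class TestOrientationCorrection:
    EDGES = np.linspace(0, 1, 21)

    def _density(self, values):
        h, _ = np.histogram(values, bins=self.EDGES, density=True)
        return h

    def test_zero_fraction_is_identity(self):
        h = self._density(np.random.default_rng(0).normal(0.3, 0.05, 500))
        out = correct_orientation_histogram(h, np.ones_like(h), self.EDGES,
                                            inverted_fraction=0.0)
        assert np.allclose(out, h)

    def test_exact_algebraic_inversion(self):
        rng = np.random.default_rng(1)
        sig = self._density(rng.normal(0.2, 0.04, 20000))
        ref = self._density(rng.normal(0.4, 0.04, 20000))
        mix = 0.5 * sig + 0.5 * ref
        out = correct_orientation_histogram(mix, ref, self.EDGES, 0.5)
        assert np.allclose(out, sig, atol=1e-9)

    @given(st.integers(0, 10_000), st.floats(0.05, 0.9))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_inversion_identity_property(self, seed, f):
        rng = np.random.default_rng(seed)
        widths = np.diff(self.EDGES)
        sig = rng.random(20)
        ref = rng.random(20)
        sig = sig / np.sum(sig * widths)
        ref = ref / np.sum(ref * widths)
        mix = (1 - f) * sig + f * ref
        out = correct_orientation_histogram(mix, ref, self.EDGES, f)
        assert np.allclose(out, sig, atol=1e-8)

    def test_fraction_one_rejected(self):
        h = np.ones(20)
        with pytest.raises(ParameterError):
            correct_orientation_histogram(h, h, self.EDGES, 1.0)

    def test_misfit_reference_warns(self):
        sig = np.zeros(20)
        sig[3] = 1 / np.diff(self.EDGES)[0] / 1.0
        ref = np.zeros(20)
        ref[15] = sig[3]
        with pytest.warns(UserWarning):
            correct_orientation_histogram(sig, ref, self.EDGES, 0.5)


class TestMixtureFit:
    def test_well_separated_clusters(self):
        rng = np.random.default_rng(2)
        e = np.concatenate((rng.normal(0.2, 0.01, 400),
                            rng.normal(0.4, 0.01, 400)))
        fit = fit_gaussian_mixture(e)
        assert fit.means[0] == pytest.approx(0.2, abs=0.02)
        assert fit.means[1] == pytest.approx(0.4, abs=0.02)

    def test_single_cluster_flagged_overlapping(self):
        rng = np.random.default_rng(3)
        fit = fit_gaussian_mixture(rng.normal(0.3, 0.05, 500))
        assert fit.overlapping

    def test_weight_recovery_50_50(self):
        rng = np.random.default_rng(4)
        e = np.concatenate((rng.normal(0.2, 0.05, 3000),
                            rng.normal(0.45, 0.05, 3000)))
        fit = fit_gaussian_mixture(e)
        assert abs(fit.weights[0] - 0.5) < 0.05

    def test_too_few_observations_rejected(self):
        with pytest.raises(ParameterError):
            fit_gaussian_mixture(np.full(10, 0.3))
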