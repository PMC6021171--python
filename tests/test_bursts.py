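"""Photon-stream I/O, background estimation, DCBS and E/S computation."""

import numpy as np
import pytest

from plugdyn.bursts import (
    BurstSet,
    CorrectionFactors,
    DataError,
    FormatError,
    ParameterError,
    PhotonStream,
    compute_burst_es,
    corrected_efficiency,
    estimate_background,
    filter_bursts,
    read_photon_stream,
    search_bursts_dcbs,
    write_photon_stream,
)

CLOCK = 80e6  # ticks/s


def poisson_stream(rate, duration, seed=0, channel=0):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0, duration, n))
    return PhotonStream(
        timestamps=(t * CLOCK).astype(np.int64),
        channel=np.full(n, channel, dtype=np.uint8),
        clock_rate=CLOCK, alternation_period_ticks=3200, duty_cycle=0.4)


class TestIO:
    def test_round_trip_is_lossless(self, confocal_stream, tmp_path):
        p = tmp_path / "s.h5"
        write_photon_stream(confocal_stream, p)
        back = read_photon_stream(p)
        assert np.array_equal(back.timestamps, confocal_stream.timestamps)
        assert np.array_equal(back.channel, confocal_stream.channel)
        assert np.array_equal(back.excitation, confocal_stream.excitation)
        assert back.clock_rate == confocal_stream.clock_rate

    def test_per_photon_slots_accepted_without_alternation_metadata(self):
        s = PhotonStream(timestamps=np.array([0, 10, 20], dtype=np.int64),
                         channel=np.array([0, 1, 0], dtype=np.uint8),
                         clock_rate=CLOCK,
                         excitation=np.array([0, 1, 0], dtype=np.uint8))
        assert s.alternation_period_ticks is None

    def test_unsorted_timestamps_rejected(self):
        with pytest.raises(DataError):
            PhotonStream(timestamps=np.array([10, 5], dtype=np.int64),
                         channel=np.zeros(2, dtype=np.uint8),
                         clock_rate=CLOCK, alternation_period_ticks=3200)

    def test_stream_without_any_slot_information_rejected(self):
        with pytest.raises(FormatError):
            PhotonStream(timestamps=np.array([0, 1], dtype=np.int64),
                         channel=np.zeros(2, dtype=np.uint8),
                         clock_rate=CLOCK)


class TestBackground:
    def test_pure_poisson_rate_recovered_within_5pct(self):
        # the same 1 kHz process feeds every sub-stream it belongs to
        s = poisson_stream(1000.0, 30.0, seed=1, channel=0)
        bg = estimate_background(s, window_s=30.0)
        # donor-channel photons in Dex slots arrive at 400 Hz (duty cycle)
        est = bg.mean_rate("dd")
        assert abs(est - 400.0) / 400.0 < 0.05

    def test_two_segment_rates_recovered(self):
        rng = np.random.default_rng(2)
        t1 = np.sort(rng.uniform(0, 20, rng.poisson(500 * 20)))
        t2 = np.sort(rng.uniform(20, 40, rng.poisson(2000 * 20)))
        t = np.concatenate((t1, t2))
        s = PhotonStream(timestamps=(t * CLOCK).astype(np.int64),
                         channel=np.zeros(len(t), dtype=np.uint8),
                         clock_rate=CLOCK, alternation_period_ticks=3200)
        bg = estimate_background(s, window_s=20.0)
        r = bg.rates["dex_total"]
        assert abs(r[0] - 200.0) / 200.0 < 0.10   # 500 Hz x 40% duty
        assert abs(r[1] - 800.0) / 800.0 < 0.10

    def test_empty_stream_rejected(self):
        s = PhotonStream(timestamps=np.empty(0, dtype=np.int64),
                         channel=np.empty(0, dtype=np.uint8),
                         clock_rate=CLOCK, alternation_period_ticks=3200)
        with pytest.raises(DataError):
            estimate_background(s)


def _cluster_stream(seed=3, duration=10.0, bg_rate=500.0, n_cluster=100,
                    cluster_t=5.0, cluster_width=1e-3, dual=True):
    """Sparse background plus one dense photon cluster."""
    rng = np.random.default_rng(seed)
    n_bg = rng.poisson(bg_rate * duration)
    t = list(rng.uniform(0, duration, n_bg))
    ch = list(rng.integers(0, 2, n_bg))
    tc = rng.uniform(cluster_t, cluster_t + cluster_width, n_cluster)
    t += list(tc)
    # cluster photons split between donor and acceptor channels so both the
    # Dex stream and (via slot assignment) the AexAem stream light up
    ch += list(rng.integers(0, 2, n_cluster)) if dual else [0] * n_cluster
    t = np.asarray(t)
    order = np.argsort(t)
    ticks = (t[order] * CLOCK).astype(np.int64)
    stream = PhotonStream(timestamps=ticks,
                          channel=np.asarray(ch)[order].astype(np.uint8),
                          clock_rate=CLOCK, alternation_period_ticks=3200,
                          duty_cycle=0.4)
    if not dual:
        # force the cluster photons into donor-excitation slots only by
        # relabelling: acceptor-excitation acceptor stream stays silent
        exc = stream.excitation.copy()
        sel = (ticks >= cluster_t * CLOCK)
        exc[sel & (stream.channel == 1)] = 0
        stream.excitation = exc
    return stream


def _brute_force_dcbs(stream, bg, m, F):
    """Independent oracle: scan every m-photon window in each sub-stream,
    mark covered photons, intersect the hot time spans, count photons."""
    from plugdyn.bursts import _substream_mask

    t = stream.times_s

    def hot_spans(tk, key):
        hot = np.zeros(len(tk), dtype=bool)
        for i in range(len(tk) - m + 1):
            width = tk[i + m - 1] - tk[i]
            if m / max(width, 1e-12) > F * bg.rate_at(tk[i], key):
                hot[i:i + m] = True
        spans = []
        i = 0
        while i < len(tk):
            if hot[i]:
                j = i
                while j + 1 < len(tk) and hot[j + 1]:
                    j += 1
                spans.append((tk[i], tk[j]))
                i = j + 1
            else:
                i += 1
        return spans

    spans_d = hot_spans(t[_substream_mask(stream, "dex_total")], "dex_total")
    spans_a = hot_spans(t[_substream_mask(stream, "aex_acceptor")],
                        "aex_acceptor")
    classified = (_substream_mask(stream, "dd") | _substream_mask(stream, "da")
                  | _substream_mask(stream, "aa"))
    bursts = []
    for lo1, hi1 in spans_d:
        for lo2, hi2 in spans_a:
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            if lo <= hi:
                n = int(np.sum((t >= lo) & (t <= hi) & classified))
                if n >= 2:
                    bursts.append((lo, hi, n))
    return bursts


class TestDCBS:
    def test_single_dense_cluster_found_as_one_burst(self):
        s = _cluster_stream()
        bg = estimate_background(s, window_s=10.0)
        bs = search_bursts_dcbs(s, bg, m=10, F=6.0)
        oracle = _brute_force_dcbs(s, bg, m=10, F=6.0)
        assert len(bs) == 1 and len(oracle) == 1
        # implementation matches the brute-force definition exactly
        assert bs.df["size"].iloc[0] == oracle[0][2]
        assert bs.df["t_start_s"].iloc[0] == pytest.approx(oracle[0][0])
        # and the burst captures the bulk of the 100-photon cluster
        assert bs.df["size"].iloc[0] >= 60

    def test_donor_only_cluster_not_a_burst(self):
        s = _cluster_stream(dual=False)
        bg = estimate_background(s, window_s=10.0)
        bs = search_bursts_dcbs(s, bg, m=10, F=6.0)
        assert len(bs) == 0

    def test_pure_background_yields_no_bursts(self):
        s = poisson_stream(1500.0, 10.0, seed=5)
        # give it both channels so sub-streams are populated
        rng = np.random.default_rng(6)
        s.channel = rng.integers(0, 2, len(s)).astype(np.uint8)
        bg = estimate_background(s, window_s=10.0)
        bs = search_bursts_dcbs(s, bg, m=10, F=6.0)
        assert len(bs) <= 1     # < 1 false positive per 10 s

    def test_invalid_parameters_rejected(self, confocal_stream, background):
        with pytest.raises(ParameterError):
            search_bursts_dcbs(confocal_stream, background, m=1)
        with pytest.raises(ParameterError):
            search_bursts_dcbs(confocal_stream, background, F=0.5)

    def test_search_invariant_to_timestamp_offset(self):
        s = _cluster_stream(seed=9)
        bg = estimate_background(s, window_s=10.0)
        b1 = search_bursts_dcbs(s, bg, m=10, F=6.0)
        shift = 3200 * 1000     # whole alternation periods keep slots intact
        s2 = PhotonStream(timestamps=s.timestamps + shift, channel=s.channel,
                          clock_rate=s.clock_rate,
                          alternation_period_ticks=s.alternation_period_ticks,
                          duty_cycle=s.duty_cycle)
        bg2 = estimate_background(s2, window_s=10.0)
        b2 = search_bursts_dcbs(s2, bg2, m=10, F=6.0)
        assert len(b1) == len(b2)
        assert np.allclose(b1.df["size"], b2.df["size"])

    def test_detected_bursts_overlap_true_transits(self, confocal_stream,
                                                   background):
        """>= 95 % of detected bursts are dominated by real emitter photons."""
        bs = search_bursts_dcbs(confocal_stream, background)
        assert len(bs) > 10
        good = 0
        for row in bs.df.itertuples():
            pid = confocal_stream.particle[int(row.i_start):int(row.i_stop)]
            good += np.mean(pid >= 0) > 0.5
        assert good / len(bs) >= 0.95


class TestEfficiencyStoichiometry:
    def test_proximity_ratio_and_stoichiometry_arithmetic(self):
        df = _make_burst_df(n_dd=50, n_da=50, n_aa=100)
        out = compute_burst_es(BurstSet(df=df)).df
        assert out["PR"].iloc[0] == pytest.approx(0.5)
        assert out["S"].iloc[0] == pytest.approx(0.5)

    def test_zero_acceptor_gives_zero_pr(self):
        df = _make_burst_df(n_dd=80, n_da=0, n_aa=10)
        out = compute_burst_es(BurstSet(df=df)).df
        assert out["PR"].iloc[0] == 0.0

    def test_leakage_correction_hand_value(self):
        # n_DD=90, n_DA=10, l=0.1, d=0, gamma=1 -> E = 1/91
        corr = CorrectionFactors(leakage=0.1)
        e = corrected_efficiency(90, 10, 100, corr)
        assert e == pytest.approx(1.0 / 91.0)

    def test_no_donor_signal_flagged_undefined(self):
        df = _make_burst_df(n_dd=0, n_da=0, n_aa=100)
        out = compute_burst_es(BurstSet(df=df)).df
        assert bool(out["E_undefined"].iloc[0])
        assert np.isnan(out["PR"].iloc[0])

    def test_static_species_pr_variance_is_binomial(self):
        """PR spread of a static emitter matches sqrt(E(1-E)/n) within 10 %."""
        rng = np.random.default_rng(12)
        n = 100
        e_true = 0.3
        n_da = rng.binomial(n, e_true, 2000)
        pr = n_da / n
        expected_sd = np.sqrt(e_true * (1 - e_true) / n)
        assert abs(pr.std() - expected_sd) / expected_sd < 0.10


class TestFilter:
    def test_closed_interval_retention(self):
        df = _make_burst_df_many(s_values=[0.2, 0.25, 0.5, 0.75, 0.8])
        out = filter_bursts(df, s_min=0.25, s_max=0.75, min_size=0)
        assert sorted(out.df["S"].round(2)) == [0.25, 0.5, 0.75]

    def test_oversized_min_size_empties_set_with_warning(self, burst_set):
        with pytest.warns(UserWarning):
            out = filter_bursts(burst_set, min_size=10**9)
        assert len(out) == 0

    def test_invalid_window_rejected(self, burst_set):
        with pytest.raises(ParameterError):
            filter_bursts(burst_set, s_min=0.8, s_max=0.2)

    def test_donor_only_species_removed(self):
        df = _make_burst_df(n_dd=100, n_da=20, n_aa=0)     # S = 1
        out = filter_bursts(compute_burst_es(BurstSet(df=df)), min_size=0)
        assert len(out) == 0


def _make_burst_df(n_dd, n_da, n_aa):
    import pandas as pd
    return pd.DataFrame([dict(
        i_start=0, i_stop=n_dd + n_da + n_aa, t_start_s=0.0, t_stop_s=1e-3,
        duration_s=1e-3, n_DD=n_dd, n_DA=n_da, n_AA=n_aa,
        n_DD_corr=float(n_dd), n_DA_corr=float(n_da), n_AA_corr=float(n_aa),
        size=n_dd + n_da + n_aa)])


def _make_burst_df_many(s_values):
    import pandas as pd
    rows = []
    for i, s in enumerate(s_values):
        dex = 100.0
        aa = dex * (1 - s) / s
        rows.append(dict(i_start=0, i_stop=0, t_start_s=float(i),
                         t_stop_s=i + 1e-3, duration_s=1e-3,
                         n_DD=50, n_DA=50, n_AA=int(aa),
                         n_DD_corr=50.0, n_DA_corr=50.0, n_AA_corr=aa,
                         size=int(100 + aa)))
    return compute_burst_es(BurstSet(df=pd.DataFrame(rows)))
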