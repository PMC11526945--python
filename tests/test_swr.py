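"""Sharp-wave-ripple content scoring and (co)activation."""

import numpy as np
import pytest

from prospectcode import swr as SW
from prospectcode.config import PipelineConfig
from prospectcode.geometry import FOLDED_BINS
from prospectcode.session import SwrEvent


def _decoding(posterior, rel=None):
    n_t, n_x = posterior.shape
    rel = rel if rel is not None else (np.arange(n_x) - n_x // 2) * 3.0
    d = SW.SwrDecoding(
        event_id=0, midpoint_s=1.0, posterior=posterior, rel_centers=rel,
        time_centers=(np.arange(n_t) - n_t / 2 + 0.5) * 0.025,
        animal_position=171.0, in_reward_zone=True,
    )
    d.prospective_ratio, d.ratio_defined = SW.swr_prospective_ratio(d)
    return d


def _mass(rel_deg, n_t=10, n_x=60):
    post = np.full((n_t, n_x), np.nan)
    xc = (np.arange(n_x) - n_x // 2) * 3.0
    post[0] = 0.0
    post[0, np.argmin(np.abs(xc - rel_deg))] = 1.0
    return post


def test_all_forward_mass_gives_ratio_one():
    d = _decoding(_mass(30.0))
    assert d.ratio_defined
    assert d.prospective_ratio == pytest.approx(1.0)


def test_all_behind_mass_gives_ratio_minus_one():
    d = _decoding(_mass(-30.0))
    assert d.prospective_ratio == pytest.approx(-1.0)


def test_balanced_mass_gives_zero():
    post = np.full((10, 60), np.nan)
    xc = (np.arange(60) - 30) * 3.0
    post[0] = 0.0
    post[0, np.argmin(np.abs(xc - 30))] = 0.5
    post[0, np.argmin(np.abs(xc + 30))] = 0.5
    assert _decoding(post).prospective_ratio == pytest.approx(0.0)


def test_local_and_edge_mass_excluded_from_windows():
    # mass only at |rel| < 9 (local) and |rel| > 63 (edges): F + B = 0
    post = np.full((10, 60), np.nan)
    xc = (np.arange(60) - 30) * 3.0
    post[0] = 0.0
    post[0, np.argmin(np.abs(xc - 3))] = 0.4     # local band
    post[0, np.argmin(np.abs(xc - 75))] = 0.3    # beyond 63
    post[0, np.argmin(np.abs(xc + 81))] = 0.3
    d = _decoding(post)
    assert not d.ratio_defined
    assert np.isnan(d.prospective_ratio)


def test_mirror_antisymmetry():
    rng = np.random.default_rng(0)
    post = np.vstack([rng.uniform(0, 1, (4, 60)), np.full((6, 60), np.nan)])
    d = _decoding(post.copy())
    mirror = (60 - np.arange(60)) % 60
    d_m = _decoding(post[:, mirror].copy())
    assert d_m.prospective_ratio == pytest.approx(-d.prospective_ratio, abs=1e-12)


def test_windows_match_brute_force():
    rng = np.random.default_rng(1)
    cfg = PipelineConfig()
    xc = (np.arange(60) - 30) * 3.0
    for _ in range(50):
        post = rng.uniform(0, 1, (10, 60))
        d = _decoding(post.copy())
        f = sum(post[i, j] for i in range(10) for j in range(60)
                if 9 < xc[j] <= 63)
        b = sum(post[i, j] for i in range(10) for j in range(60)
                if -63 <= xc[j] < -9)
        assert d.prospective_ratio == pytest.approx((f - b) / (f + b), abs=1e-9)


def test_fraction_prospective_count():
    decs = []
    for r in (0.5, 0.2, -0.3, 0.05):
        d = _decoding(_mass(30.0))
        d.prospective_ratio, d.ratio_defined = r, True
        decs.append(d)
    assert SW.fraction_prospective(decs) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        SW.fraction_prospective([])


# --- decoding of events


def _rates_and_spikes():
    """Three cells with disjoint folded fields and spikes inside one event."""
    rates = np.full((3, 60), 0.01)
    rates[0, 20] = 20.0   # 61.5 deg
    rates[1, 40] = 20.0   # 121.5
    rates[2, 50] = 20.0   # 151.5
    return rates


def test_single_spike_event_dropped():
    ev = SwrEvent(start_s=0.9, end_s=1.1, peak_envelope=5, power_ratio=8)
    out = SW.decode_swr(
        ev, 0, [np.array([1.0]), np.array([]), np.array([])],
        _rates_and_spikes(), FOLDED_BINS, 100.0, True,
    )
    assert out is None


def test_forward_replay_decodes_forward():
    ev = SwrEvent(start_s=0.9, end_s=1.1, peak_envelope=5, power_ratio=8)
    # animal at folded 60 deg; spikes from cells at 121.5 -> +61.5 ahead
    spikes = [np.array([]), np.array([0.99, 1.0, 1.01]), np.array([])]
    d = SW.decode_swr(ev, 0, spikes, _rates_and_spikes(), FOLDED_BINS, 60.0, True)
    assert d is not None
    peak_rel = d.rel_centers[np.nanargmax(np.nansum(d.posterior[d.decoded], axis=0))]
    assert 55 <= peak_rel <= 65
    assert d.prospective_ratio > 0.9


def test_sequenceless_matches_single_bin_decode():
    from prospectcode.decoding import decode_window

    ev = SwrEvent(start_s=0.9, end_s=1.1, peak_envelope=5, power_ratio=8)
    spikes = [np.array([0.95, 1.05]), np.array([1.0]), np.array([])]
    rates = _rates_and_spikes()
    rel, degenerate = SW.sequenceless_decode(ev, spikes, rates, FOLDED_BINS, 60.0)
    counts = np.array([2, 1, 0])
    post = decode_window(counts, rates, 0.2)
    expected_abs = FOLDED_BINS.centers[np.argmax(post)]
    from prospectcode.geometry import circ_diff

    assert rel == pytest.approx(float(circ_diff(expected_abs, 60.0, period=180.0)))
    assert not degenerate


def test_sequenceless_uniform_is_degenerate():
    ev = SwrEvent(start_s=0.9, end_s=1.1, peak_envelope=5, power_ratio=8)
    rates = np.full((2, 60), 1.0)
    rel, degenerate = SW.sequenceless_decode(
        ev, [np.array([0.95]), np.array([1.0])], rates, FOLDED_BINS, 60.0
    )
    assert degenerate


def test_sequenceless_under_spike_minimum_dropped():
    ev = SwrEvent(start_s=0.9, end_s=1.1, peak_envelope=5, power_ratio=8)
    out = SW.sequenceless_decode(
        ev, [np.array([1.0]), np.array([])], _rates_and_spikes(), FOLDED_BINS, 60.0
    )
    assert out is None


# --- unoccupied zone


def test_unoccupied_zone_planted_peak_flagged():
    rel = (np.arange(180) - 90) * 2.0
    post = np.full((10, 180), 1.0 / 180)
    post[:, np.abs(rel) >= 162] = 0.05
    d = SW.SwrDecoding(
        event_id=0, midpoint_s=1.0, posterior=post, rel_centers=rel,
        time_centers=np.arange(10) * 0.025, animal_position=80.0, in_reward_zone=True,
    )
    flagged, degenerate = SW.unoccupied_zone_swr(d)
    assert flagged and not degenerate


def test_unoccupied_zone_uniform_degenerate():
    rel = (np.arange(180) - 90) * 2.0
    post = np.full((10, 180), 1.0 / 180)
    d = SW.SwrDecoding(
        event_id=0, midpoint_s=1.0, posterior=post, rel_centers=rel,
        time_centers=np.arange(10) * 0.025, animal_position=80.0, in_reward_zone=True,
    )
    flagged, degenerate = SW.unoccupied_zone_swr(d)
    assert not flagged and degenerate


# --- activation / coactivation


def test_activation_and_coactivation_brute_force():
    rng = np.random.default_rng(2)
    events = [SwrEvent(start_s=10 * k, end_s=10 * k + 0.1, peak_envelope=1, power_ratio=8)
              for k in range(20)]
    unit_ids = list(range(6))
    trains = [np.sort(rng.uniform(0, 200, 120)) for _ in unit_ids]
    act, coact = SW.activation_coactivation(unit_ids, trains, events)

    def fired(i, ev):
        return np.any((trains[i] >= ev.start_s) & (trains[i] <= ev.end_s))

    for i in unit_ids:
        expected = np.mean([fired(i, ev) for ev in events])
        assert act.loc[act.unit_id == i, "activation"].iloc[0] == pytest.approx(expected)
    for _, row in coact.iterrows():
        i, j = int(row.unit_a), int(row.unit_b)
        expected = np.mean([fired(i, ev) and fired(j, ev) for ev in events])
        assert row.coactivation == pytest.approx(expected)
        # coactivation can never exceed either cell's activation
        for c in (i, j):
            assert row.coactivation <= act.loc[act.unit_id == c, "activation"].iloc[0] + 1e-12


def test_cell_firing_every_event_has_activation_one():
    events = [SwrEvent(start_s=k, end_s=k + 0.1, peak_envelope=1, power_ratio=8)
              for k in range(5)]
    trains = [np.array([k + 0.05 for k in range(5)]), np.array([0.05])]
    act, coact = SW.activation_coactivation([0, 1], trains, events)
    assert act.activation.iloc[0] == 1.0
    assert act.activation.iloc[1] == 0.2


def test_disjoint_cells_have_zero_coactivation():
    events = [SwrEvent(start_s=k, end_s=k + 0.1, peak_envelope=1, power_ratio=8)
              for k in range(4)]
    trains = [np.array([0.05, 2.05]), np.array([1.05, 3.05])]
    _, coact = SW.activation_coactivation([0, 1], trains, events)
    assert coact.coactivation.iloc[0] == 0.0


def test_zero_events_rejected():
    with pytest.raises(ValueError):
        SW.activation_coactivation([0], [np.array([1.0])], [])
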