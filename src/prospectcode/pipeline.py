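"""End-to-end session pipeline and group-change conventions.

Runs behavior segmentation, LFP state detection, unit quality control,
spike-field coupling, place-field identification, cross-validated
decoding, theta-sequence scoring and SWR content scoring on one session,
and exports tidy per-unit / per-trial / per-event tables for external
group statistics (the study's linear mixed-effects models are fitted
outside this package).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import lfp as lfpmod
from . import placefields as pf
from . import spikefield as sf
from . import swr as swrmod
from . import theta as thetamod
from . import units as unitsmod
from .config import PPC_BANDS, PipelineConfig
from .decoding import cross_validated_decode, session_qc
from .placefields import MapBuilder
from .session import Session


def run_pipeline(session: Session, cfg: PipelineConfig | None = None) -> dict:
    """Run all stages on one session; returns tables plus a run manifest."""
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    counts: dict[str, int] = {}
    result: dict[str, object] = {"config": asdict(cfg)}

    # --- behavior
    trace = beh.smooth_trace(session.behavior, _smooth_window(session.behavior))
    trials = beh.segment_trials(trace, session.geometry)
    beh.classify_trials(trials, trace, session.geometry)
    n_correct = sum(t.label == "correct" for t in trials)
    if n_correct >= 2:
        beh.split_fast_slow(trials)
    counts["trials"] = len(trials)
    counts["correct_trials"] = n_correct
    result["trials"] = beh.trial_table(trials)

    # --- LFP states
    pyr_channel = lfpmod.select_pyramidal_channel(session.lfp)
    pyr = session.lfp.channel(pyr_channel)
    states = lfpmod.detect_theta_nontheta(pyr, session.lfp.rate, cfg)
    states.swr_events = [
        e
        for e in lfpmod.detect_swr(pyr, session.lfp.rate, cfg)
        if states.in_nontheta(np.array([e.midpoint_s]))[0]
    ]
    session.states = states
    counts["theta_periods"] = len(states.theta_periods)
    counts["swr_events"] = len(states.swr_events)
    result["swr_summary"] = lfpmod.swr_summary(states.swr_events, states.nontheta_periods)
    result["state_table"] = _state_table(states)

    # --- units
    included = unitsmod.quality_filter(session.units, cfg)
    unitsmod.classify_units(included, cfg)
    pyramidal = [u for u in included if u.cell_type == "pyramidal"]
    counts["units_included"] = len(included)
    counts["pyramidal"] = len(pyramidal)

    # --- spike-field coupling
    ppc_rows = []
    vr_intervals = sf.ppc_trials_for_epoch("VR", trials=trials)
    for band_name, band in PPC_BANDS.items():
        phase = sf.instantaneous_phase(pyr, band, session.lfp.rate, cfg=cfg)
        for u in included:
            res = sf.compute_ppc(
                u.spike_times, phase, session.lfp.rate, vr_intervals, cfg,
                unit_id=u.unit_id, band=band_name, epoch="VR",
            )
            ppc_rows.append(
                {
                    "unit_id": u.unit_id,
                    "region": u.region,
                    "cell_type": u.cell_type,
                    "band": band_name,
                    "epoch": "VR",
                    "ppc": res.ppc,
                    "n_spikes": res.n_spikes,
                    "n_trials": res.n_trials,
                    "included": res.included,
                }
            )
    result["ppc"] = pd.DataFrame(ppc_rows)

    # --- place fields
    records, folded_maps = pf.identify_place_cells(
        pyramidal, trace, session.geometry, cfg, rng
    )
    result["place_cells"] = pf.place_cell_table(records)
    place_ids = {r.unit_id for r in records if r.is_place_cell}
    place_units = [u for u in pyramidal if u.unit_id in place_ids]
    counts["place_cells"] = len(place_units)

    # --- decoding + QC
    excluded = False
    if n_correct >= cfg.n_folds and place_units:
        cv = cross_validated_decode(
            place_units, trace, trials, session.geometry, cfg, rng
        )
        qc_ok = session_qc(cv, cfg)
        result["decoding_qc"] = {
            "median_error_deg": cv.median_error,
            "normalized_prob": cv.normalized_prob,
            "included": qc_ok,
        }
        excluded = not qc_ok
    else:
        result["decoding_qc"] = {"median_error_deg": np.nan, "normalized_prob": np.nan, "included": False}
        excluded = True

    # --- theta and SWR coding
    theta_tbl = pd.DataFrame()
    swr_tbl = pd.DataFrame()
    theta_sig = {"significant": False, "quadrant_ratio": np.nan}
    if not excluded:
        folded_builder = MapBuilder(trace, session.geometry, folded=True, cfg=cfg)
        rates = np.array([folded_maps[u.unit_id].rates for u in place_units])
        spike_trains = [u.spike_times for u in place_units]

        troughs = thetamod.extract_theta_cycles(
            pyr, session.lfp.rate, trace, states, trials, cfg
        )
        decodings = []
        trial_of = _trial_lookup(trials)
        for tr_t in troughs:
            apos = session.geometry.fold(trace.position_at(np.array([tr_t]))[0])
            d = thetamod.decode_theta_cycle(
                tr_t, spike_trains, rates, folded_builder.bins, apos, cfg
            )
            if d is not None:
                d.trial_id = trial_of(tr_t)
                decodings.append(d)
        counts["theta_cycles_decoded"] = len(decodings)
        if decodings:
            sig, qr, _ = thetamod.sequence_significance(decodings, cfg, rng)
            theta_sig = {"significant": sig, "quadrant_ratio": qr}
            theta_tbl = thetamod.prospective_by_position_and_speed(
                decodings, trials, session.geometry, cfg
            )

        swr_decs = []
        for k, ev in enumerate(states.swr_events):
            apos_abs = trace.position_at(np.array([ev.midpoint_s]))[0]
            in_rz = bool(session.geometry.in_reward_zone(np.array([apos_abs]))[0])
            if not in_rz:
                continue
            d = swrmod.decode_swr(
                ev, k, spike_trains, rates, folded_builder.bins,
                session.geometry.fold(apos_abs), in_rz, cfg,
            )
            if d is not None:
                swr_decs.append(d)
        counts["swr_decoded"] = len(swr_decs)
        if swr_decs:
            swr_tbl = swrmod.swr_event_table(swr_decs)
        act, coact = swrmod.activation_coactivation(
            [u.unit_id for u in place_units], spike_trains, states.swr_events
        ) if states.swr_events else (pd.DataFrame(), pd.DataFrame())
        result["swr_activation"] = act
        result["swr_coactivation"] = coact
    result["theta_significance"] = theta_sig
    result["theta_coding"] = theta_tbl
    result["swr_coding"] = swr_tbl
    result["excluded_by_qc"] = excluded

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config_overrides": {k: str(v) for k, v in cfg.overrides().items()},
        "seed": cfg.seed,
        "counts": counts,
    }
    result["manifest"] = manifest
    return result


def _smooth_window(trace) -> int:
    # default 0.5 s moving average on 50 Hz behavior
    return max(1, int(round(0.5 / trace.dt)))


def _trial_lookup(trials):
    def lookup(t: float) -> int:
        for tr in trials:
            if tr.start_s <= t < tr.end_s:
                return tr.trial_id
        return -1

    return lookup


def _state_table(states) -> pd.DataFrame:
    rows = [
        {"kind": "theta", "start_s": a, "end_s": b, "duration_ms": 1000 * (b - a),
         "size": np.nan, "power_ratio": np.nan}
        for a, b in states.theta_periods
    ] + [
        {"kind": "nontheta", "start_s": a, "end_s": b, "duration_ms": 1000 * (b - a),
         "size": np.nan, "power_ratio": np.nan}
        for a, b in states.nontheta_periods
    ] + [
        {"kind": "swr", "start_s": e.start_s, "end_s": e.end_s,
         "duration_ms": e.duration_ms, "size": e.peak_envelope,
         "power_ratio": e.power_ratio}
        for e in states.swr_events
    ]
    return pd.DataFrame(rows, columns=["kind", "start_s", "end_s", "duration_ms", "size", "power_ratio"])


def save_results(result: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, val in result.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{key}.csv", index=False)
        elif isinstance(val, dict):
            (out / f"{key}.json").write_text(json.dumps(val, default=_jsonify, indent=1))
    (out / "excluded_by_qc.json").write_text(json.dumps(bool(result.get("excluded_by_qc", False))))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)


def group_change(metric_group: float, metric_reference: float, as_percent: bool = True) -> float:
    """Group difference relative to |reference|: percent or fold change."""
    if metric_reference == 0:
        raise ValueError("reference metric is zero; change undefined")
    fold = (metric_group - metric_reference) / abs(metric_reference)
    return 100.0 * fold if as_percent else fold
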