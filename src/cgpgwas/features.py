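"""Scalar phenotypes of a converged beat.

Sixteen features: for each of the action potential (voltage, mV) and the
calcium transient (cytosolic calcium, uM) the initial value (base), peak,
amplitude (peak - base), time to peak, and the times from stimulus onset to
25/50/75/90% recovery from peak back towards base (APD_x / CTD_x, measured by
linear interpolation of the first post-peak crossing).
"""

from __future__ import annotations

import numpy as np

from .cellmodel import BeatWaveforms

__all__ = ["FEATURE_NAMES", "AP_FEATURES", "CT_FEATURES", "extract_trace_features",
           "extract_features", "feature_table"]

_LEVELS = (25, 50, 75, 90)

AP_FEATURES = ["apbase", "apamp", "appeak", "apttp"] + [f"apd{x}" for x in _LEVELS]
CT_FEATURES = ["ctbase", "ctamp", "ctpeak", "ctttp"] + [f"ctd{x}" for x in _LEVELS]
FEATURE_NAMES = AP_FEATURES + CT_FEATURES


def extract_trace_features(time: np.ndarray, trace: np.ndarray, prefix: str) -> dict[str, float]:
    """Base/peak/amplitude/timing features of one beat-relative trace.

    Durations are the time from stimulus onset (t = time[0]) until the trace
    first falls below peak - (x/100) * amplitude after the peak, located by
    linear interpolation; NaN (flagged undefined) if the trace never
    recrosses the level within the beat, or if the amplitude is zero.
    """
    t0 = time[0]
    base = float(trace[0])
    ipeak = int(np.argmax(trace))
    peak = float(trace[ipeak])
    amp = peak - base
    out = {
        f"{prefix}base": base,
        f"{prefix}peak": peak,
        f"{prefix}amp": amp,
        f"{prefix}ttp": float(time[ipeak] - t0),
    }
    for x in _LEVELS:
        name = f"{prefix}d{x}"
        if amp <= 0.0:
            out[name] = np.nan
            continue
        level = peak - (x / 100.0) * amp
        seg = trace[ipeak:]
        below = np.flatnonzero(seg < level)
        if below.size == 0 or below[0] == 0:
            out[name] = np.nan
            continue
        k = below[0]
        t_hi, t_lo = time[ipeak + k - 1], time[ipeak + k]
        y_hi, y_lo = seg[k - 1], seg[k]
        frac = (y_hi - level) / (y_hi - y_lo)
        out[name] = float(t_hi + frac * (t_lo - t_hi) - t0)
    return out


def extract_features(beat: BeatWaveforms) -> dict[str, float]:
    """All 16 features of a converged beat; refuses non-converged beats."""
    if beat.status != "converged":
        raise ValueError("feature extraction requires a converged beat")
    feats = extract_trace_features(beat.time, beat.voltage, "ap")
    feats.update(extract_trace_features(beat.time, beat.calcium, "ct"))
    return feats


def feature_table(beats: list[BeatWaveforms]) -> tuple[np.ndarray, np.ndarray]:
    """Stack features for a population of beats.

    Returns (values, failed): values is (N, 16) aligned with FEATURE_NAMES
    (NaN rows for failures), failed is the per-individual failure mask.
    """
    n = len(beats)
    values = np.full((n, len(FEATURE_NAMES)), np.nan)
    failed = np.zeros(n, dtype=bool)
    for i, beat in enumerate(beats):
        if beat.status != "converged":
            failed[i] = True
            continue
        feats = extract_features(beat)
        values[i] = [feats[name] for name in FEATURE_NAMES]
    return values, failed
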