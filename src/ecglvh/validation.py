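"""Delineation-accuracy validation against the analytic ground truth.

Runs a grid of synthetic records — spanning the QRS amplitude and width
range and the heart rates the cohort generator produces, plus T-wave
amplitude variation — through the full signal chain (band-pass, R
detection, median beat, delineation) and tabulates each landmark's error
versus the template-implied truth.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import delineate, preprocess, synth
from .datatypes import LEADS

#: Landmarks of the delineation contract.
CONTRACT_LANDMARKS = (
    "p_onset", "p_pos_peak", "p_pos_end", "p_neg_peak", "p_offset",
    "qrs_onset", "q_peak", "q_end", "r_peak", "s_peak", "qrs_offset",
    "t_peak", "t_end",
)

GRID_QRS_AMPLITUDE_FACTORS = (0.7, 1.0, 1.4)
GRID_QRS_WIDTH_FACTORS = (0.85, 1.0, 1.2)
GRID_RR_MS = (800.0, 1000.0, 1200.0)
GRID_T_AMPLITUDES_MV = (0.10, 0.15, 0.22)


def grid_specs() -> list[synth.BeatTemplateSpec]:
    """The 81 beat templates of the validation grid."""
    specs = []
    for af, wf, rr, ta in itertools.product(
            GRID_QRS_AMPLITUDE_FACTORS, GRID_QRS_WIDTH_FACTORS,
            GRID_RR_MS, GRID_T_AMPLITUDES_MV):
        spec = synth.BeatTemplateSpec().scaled(
            qrs_factor=af, width_factor=wf, rr_interval_ms=rr)
        t = spec.waves["T"]
        spec.waves["T"] = synth.WaveSpec(ta, t.center_ms, t.sigma_ms)
        specs.append(spec)
    return specs


def delineation_errors(specs: Optional[Iterable[synth.BeatTemplateSpec]] = None,
                       noise_sd_mv: float = 0.0,
                       seed: int = 0) -> pd.DataFrame:
    """Landmark errors (ms) over the grid; absent-but-expected rows carry
    NaN error and ``absent=True``."""
    specs = list(specs) if specs is not None else grid_specs()
    rows = []
    for i, spec in enumerate(specs):
        noise = synth.NoiseSpec(baseline_wander_amp_mv=0.0,
                                white_noise_sd_mv=noise_sd_mv,
                                seed=seed + i)
        rec, truth = synth.generate_ecg(spec, noise)
        filt = preprocess.bandpass_filter(rec)
        r_peaks = preprocess.detect_r_peaks(filt, "II")
        rr = preprocess.mean_rr_ms(r_peaks, rec.fs)
        beats = preprocess.median_beat(filt, r_peaks)
        anchor = truth.beat_ms["II"]["r_peak"]
        for lead in LEADS:
            mb = beats[lead]
            fid, _ = delineate.delineate_beat(mb, rr_ms=rr)
            for lm in CONTRACT_LANDMARKS:
                tv = truth.beat_ms[lead].get(lm)
                if tv is None:
                    continue
                mv = getattr(fid, lm)
                if mv is None:
                    rows.append({"record": i, "lead": lead, "landmark": lm,
                                 "error_ms": np.nan, "absent": True})
                    continue
                meas = (mv - mb.r_index) * 1000.0 / mb.fs + anchor
                rows.append({"record": i, "lead": lead, "landmark": lm,
                             "error_ms": meas - float(tv), "absent": False})
    return pd.DataFrame(rows)


def summarise_errors(errors: pd.DataFrame, tolerance_ms: float) -> dict:
    """Fraction within tolerance (absences count as failures) + extremes."""
    within = (~errors["absent"]) & (errors["error_ms"].abs()
                                    <= tolerance_ms + 1e-9)
    return {
        "n_landmarks": int(len(errors)),
        "within_pct": 100.0 * float(within.mean()),
        "max_abs_error_ms": float(errors["error_ms"].abs().max()),
        "n_absent": int(errors["absent"].sum()),
    }
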