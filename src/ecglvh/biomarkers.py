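"""ECG biomarkers and classical LVH indices from delineated median beats.

Per-lead features (amplitudes relative to the voltage at QRS onset,
durations from wave boundaries, slopes from the filtered derivative) are
summarised into global features as the median across the independent
leads, and combined into the classical indices: Bazett/Fridericia QTc,
QT dispersion, P-wave terminal force in V1, Sokolow–Lyon and Cornell
voltage criteria, and a Minnesota-style pathological-Q flag.

The rule functions at the top accept scalars or arrays and are the single
implementation used both by the waveform pipeline and by the tabular
cohort fast path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import LEADS, MedianBeat, LeadFiducials

# Classical criterion thresholds (mV).
SOKOLOW_LYON_THRESHOLD_MV = 3.5
CORNELL_THRESHOLD_MEN_MV = 2.8
CORNELL_THRESHOLD_WOMEN_MV = 2.0
# Minnesota-style pathological Q: duration >= 40 ms or depth >= 25% of R.
PATH_Q_MIN_DUR_MS = 40.0
PATH_Q_R_FRACTION = 0.25
ST_MEASUREMENT_OFFSET_MS = 60.0  # J point + 60 ms


# ---------------------------------------------------------------------------
# Index rule functions (scalar or vectorised)
# ---------------------------------------------------------------------------

def bazett_qtc(qt_ms, rr_ms):
    """QTc = QT / sqrt(RR in s)."""
    return np.asarray(qt_ms) / np.sqrt(np.asarray(rr_ms) / 1000.0)


def fridericia_qtc(qt_ms, rr_ms):
    return np.asarray(qt_ms) / np.cbrt(np.asarray(rr_ms) / 1000.0)


def qt_dispersion(qt_by_lead):
    """max − min QT over leads; rows = records for a 2-D input."""
    qt = np.asarray(qt_by_lead, dtype=float)
    axis = -1 if qt.ndim > 1 else None
    return np.nanmax(qt, axis=axis) - np.nanmin(qt, axis=axis)


def ptf_v1(p_neg_amp_v1_mv, p_neg_dur_v1_ms):
    """P-wave terminal force in V1 (mV·ms), signed negative."""
    return -(np.abs(np.asarray(p_neg_amp_v1_mv))
             * np.asarray(p_neg_dur_v1_ms))


def sokolow_lyon_flag(s_v1_depth_mv, r_v5_mv, r_v6_mv):
    """S(V1) + max(R(V5), R(V6)) ≥ 3.5 mV (amplitudes as positive depths)."""
    total = (np.asarray(s_v1_depth_mv)
             + np.maximum(np.asarray(r_v5_mv), np.asarray(r_v6_mv)))
    return total >= SOKOLOW_LYON_THRESHOLD_MV


def cornell_flag(r_avl_mv, s_v3_depth_mv, sex):
    """R(aVL) + S(V3) > 2.8 mV in men, > 2.0 mV in women."""
    total = np.asarray(r_avl_mv) + np.asarray(s_v3_depth_mv)
    thr = np.where(np.asarray(sex) == "F",
                   CORNELL_THRESHOLD_WOMEN_MV, CORNELL_THRESHOLD_MEN_MV)
    return total > thr


def pathological_q_flag(q_dur_ms, q_depth_mv, r_amp_mv):
    """Q duration ≥ 40 ms or Q depth ≥ 25 % of the R amplitude."""
    q_dur = np.asarray(q_dur_ms, dtype=float)
    q_depth = np.asarray(q_depth_mv, dtype=float)
    r_amp = np.asarray(r_amp_mv, dtype=float)
    with np.errstate(invalid="ignore"):
        out = (q_dur >= PATH_Q_MIN_DUR_MS) | (q_depth >= PATH_Q_R_FRACTION * r_amp)
    return np.where(np.isnan(q_dur) | np.isnan(q_depth), False, out)


# ---------------------------------------------------------------------------
# Per-lead feature extraction
# ---------------------------------------------------------------------------

#: Per-lead feature names, in output order.
LEAD_FEATURES = (
    "q_amp", "r_amp", "s_amp", "qrs_amp", "q_dur", "qrs_dur",
    "asc_slope", "desc_slope", "p_pos_amp", "p_pos_dur", "p_neg_amp",
    "p_neg_dur", "p_dur", "t_amp", "t_dur", "qt", "st_dev",
)


def lead_biomarkers(beat: MedianBeat, fid: LeadFiducials) -> dict[str, float]:
    """Features for one lead; absent fiducials yield NaN, never zero.

    QRS wave amplitudes are measured with respect to the signal value at
    QRS onset; P and T amplitudes with respect to the isoelectric level.
    QRS amplitude is peak-to-trough (R − S, absent waves contributing 0).
    """
    x = beat.beat
    fs = beat.fs
    iso = beat.isoelectric_level
    ms = 1000.0 / fs
    out: dict[str, float] = {k: np.nan for k in LEAD_FEATURES}

    if fid.qrs_onset is None or fid.qrs_offset is None:
        return out
    ref = x[fid.qrs_onset]

    q_amp = x[fid.q_peak] - ref if fid.q_peak is not None else np.nan
    r_amp = x[fid.r_peak] - ref if fid.r_peak is not None else np.nan
    s_amp = x[fid.s_peak] - ref if fid.s_peak is not None else np.nan
    out["q_amp"], out["r_amp"], out["s_amp"] = q_amp, r_amp, s_amp
    if fid.r_peak is not None or fid.s_peak is not None:
        out["qrs_amp"] = (0.0 if np.isnan(r_amp) else r_amp) - \
                         (0.0 if np.isnan(s_amp) else s_amp)
    if fid.q_peak is not None and fid.q_end is not None:
        out["q_dur"] = (fid.q_end - fid.qrs_onset) * ms
    out["qrs_dur"] = (fid.qrs_offset - fid.qrs_onset) * ms

    # Up/down-stroke slopes: extreme central-difference derivative inside
    # the complex, split at the dominant peak (mV/s).
    split = fid.r_peak if fid.r_peak is not None else fid.q_peak
    if split is not None and fid.qrs_onset < split < fid.qrs_offset:
        deriv = np.gradient(x) * fs  # mV/s
        up = deriv[fid.qrs_onset:split + 1]
        down = deriv[split:fid.qrs_offset + 1]
        if len(up):
            out["asc_slope"] = float(np.max(up))
        if len(down):
            out["desc_slope"] = float(np.min(down))

    if fid.p_pos_peak is not None:
        out["p_pos_amp"] = x[fid.p_pos_peak] - iso
        if fid.p_onset is not None and fid.p_pos_end is not None:
            out["p_pos_dur"] = (fid.p_pos_end - fid.p_onset) * ms
    if fid.p_neg_peak is not None:
        out["p_neg_amp"] = x[fid.p_neg_peak] - iso
        if fid.p_pos_end is not None and fid.p_offset is not None:
            out["p_neg_dur"] = (fid.p_offset - fid.p_pos_end) * ms
    if fid.p_onset is not None and fid.p_offset is not None:
        out["p_dur"] = (fid.p_offset - fid.p_onset) * ms

    if fid.t_peak is not None:
        out["t_amp"] = x[fid.t_peak] - iso
        if fid.t_onset is not None and fid.t_end is not None:
            out["t_dur"] = (fid.t_end - fid.t_onset) * ms
    if fid.t_end is not None:
        out["qt"] = (fid.t_end - fid.qrs_onset) * ms

    j60 = fid.qrs_offset + beat.ms_to_samples(ST_MEASUREMENT_OFFSET_MS)
    if j60 < len(x):
        out["st_dev"] = abs(x[j60] - iso)
    return out


# ---------------------------------------------------------------------------
# Global and derived indices
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerVector:
    """Per-lead features, their global medians, and the derived indices."""

    per_lead: pd.DataFrame          # index = leads, columns = LEAD_FEATURES
    global_features: pd.Series      # median across leads
    ventricular_rate: float
    qtc: float
    qt_dispersion: float
    ptfv1: float
    sokolow_lyon: Optional[bool]
    cornell: Optional[bool]
    pathological_q: Optional[bool]
    rr_ms: float
    extras: dict = field(default_factory=dict)

    def to_series(self, per_lead: bool = False) -> pd.Series:
        """Flatten to one row, e.g. for a cohort-level biomarker table."""
        data = {f"ecg_{k}": v for k, v in self.global_features.items()}
        data.update({
            "ecg_rate": self.ventricular_rate,
            "ecg_qtc": self.qtc,
            "ecg_qt_disp": self.qt_dispersion,
            "ecg_ptfv1": self.ptfv1,
            "ecg_sokolow_flag": _flag_to_float(self.sokolow_lyon),
            "ecg_cornell_flag": _flag_to_float(self.cornell),
            "ecg_path_q_flag": _flag_to_float(self.pathological_q),
        })
        if per_lead:
            for lead in self.per_lead.index:
                for feat in self.per_lead.columns:
                    data[f"ecg_{feat}_{lead}"] = self.per_lead.loc[lead, feat]
        return pd.Series(data)


def _flag_to_float(flag: Optional[bool]) -> float:
    return np.nan if flag is None else float(flag)


def global_and_derived(per_lead: pd.DataFrame, rr_ms: float,
                       sex: Optional[str] = None,
                       qtc_formula: str = "bazett",
                       min_leads: int = 4) -> BiomarkerVector:
    """Summarise per-lead features into the global biomarker vector.

    ``per_lead`` must be indexed by lead name with :data:`LEAD_FEATURES`
    columns.  A global feature is the nan-median across leads and is set
    to NaN when fewer than ``min_leads`` leads contribute.  Cornell needs
    aVL, which is not an independent lead; its R amplitude is
    reconstructed linearly as R(I) − R(II)/2 (valid on median beats,
    where R peaks are synchronous across leads), clipped at zero.
    """
    if per_lead.notna().any(axis=1).sum() < min_leads:
        raise ValueError(f"need features in >= {min_leads} leads")

    glob = {}
    for feat in per_lead.columns:
        col = per_lead[feat]
        glob[feat] = col.median(skipna=True) if col.notna().sum() >= min_leads \
            else np.nan
    global_features = pd.Series(glob)

    rate = 60000.0 / rr_ms
    qt_fn = bazett_qtc if qtc_formula == "bazett" else fridericia_qtc
    qtc = float(qt_fn(global_features["qt"], rr_ms))
    qt_disp = float(qt_dispersion(per_lead["qt"].to_numpy())) \
        if per_lead["qt"].notna().sum() >= 2 else np.nan

    if {"p_neg_amp", "p_neg_dur"} <= set(per_lead.columns) and \
            not np.isnan(per_lead.loc["V1", "p_neg_amp"]) and \
            not np.isnan(per_lead.loc["V1", "p_neg_dur"]):
        ptfv1 = float(ptf_v1(per_lead.loc["V1", "p_neg_amp"],
                             per_lead.loc["V1", "p_neg_dur"]))
    else:
        ptfv1 = np.nan

    s_v1 = per_lead.loc["V1", "s_amp"]
    r_v5 = per_lead.loc["V5", "r_amp"]
    r_v6 = per_lead.loc["V6", "r_amp"]
    if np.isnan(r_v5) and np.isnan(r_v6):
        sokolow: Optional[bool] = None
    else:
        s_depth = 0.0 if np.isnan(s_v1) else -float(s_v1)
        r_max = np.nanmax([r_v5, r_v6])
        sokolow = bool(sokolow_lyon_flag(s_depth, r_max, r_max))

    if sex is None:
        cornell: Optional[bool] = None
    else:
        r_i = per_lead.loc["I", "r_amp"]
        r_ii = per_lead.loc["II", "r_amp"]
        s_v3 = per_lead.loc["V3", "s_amp"]
        if np.isnan(r_i) or np.isnan(r_ii):
            cornell = None
        else:
            r_avl = max(float(r_i) - float(r_ii) / 2.0, 0.0)
            s_depth3 = 0.0 if np.isnan(s_v3) else -float(s_v3)
            cornell = bool(cornell_flag(r_avl, s_depth3, sex))

    q_dur = per_lead["q_dur"].to_numpy(dtype=float)
    q_depth = np.abs(per_lead["q_amp"].to_numpy(dtype=float))
    r_amp = per_lead["r_amp"].to_numpy(dtype=float)
    if np.all(np.isnan(q_dur)):
        path_q: Optional[bool] = False
    else:
        path_q = bool(np.any(pathological_q_flag(q_dur, q_depth, r_amp)))

    return BiomarkerVector(
        per_lead=per_lead,
        global_features=global_features,
        ventricular_rate=rate,
        qtc=qtc,
        qt_dispersion=qt_disp,
        ptfv1=ptfv1,
        sokolow_lyon=sokolow,
        cornell=cornell,
        pathological_q=path_q,
        rr_ms=rr_ms,
    )
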