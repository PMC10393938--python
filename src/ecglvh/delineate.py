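"""Fiducial delineation of median beats.

QRS bounds follow the Hilbert-envelope tangent scheme: the analytic-
signal envelope of the baseline-corrected beat is computed, the maximum-
slope point of the envelope on each side of the R peak gives a tangent
line whose intersection with the isoelectric level is the initial bound;
the bound is then refined outward to the point where the rectified
signal falls below 1 % of the outermost wave's amplitude (with a noise-
dependent floor) — the same convention that defines wave extent
throughout the package.

Within the bounds, baseline crossings partition the complex into
sub-waves labelled Q/R/S by polarity and order around the dominant
positive deflection.  P-wave boundaries are estimated by Gaussian-width
extrapolation from the outer-flank half-maximum width (robust where a
1 %-amplitude threshold would sit below the noise).  T end uses the
tangent method: the tangent at the steepest point of the T down-slope is
intersected with the isoelectric line; T onset mirrors it on the
up-slope.

A practical wrinkle: the 1 Hz high-pass of the conditioning filter
attenuates the heart-rate fundamental of the beat train, which tilts the
median beat by a slow sinusoid at the RR frequency.  ``delineate_beat``
removes it by fitting ``a + b·cos + c·sin`` at the RR fundamental to the
isoelectric (PR and TP) segments before delineating.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.signal import butter, hilbert, find_peaks, savgol_filter, sosfiltfilt

from .datatypes import LeadFiducials, MedianBeat
from .preprocess import BAND_HZ, FILTER_ORDER

# Shared wave-extent convention (see synth.K_ONSET): boundary at the 1 %
# amplitude crossing of a Gaussian wave, i.e. peak ∓ 3.035 σ.
ONSET_FRACTION = 0.01
K_ONSET = float(np.sqrt(2.0 * np.log(1.0 / ONSET_FRACTION)))
HALF_MAX_SIGMA = 1.17741  # half-maximum of a Gaussian sits at 1.177 σ


@dataclass(frozen=True)
class DelineationConfig:
    """Search windows and floors; defaults span physiological ranges."""

    qrs_search_ms: float = 150.0     # QRS bound search, each side of R
    p_window_ms: tuple[float, float] = (250.0, 40.0)  # before QRS onset
    t_window_ms: tuple[float, float] = (80.0, 400.0)  # after QRS offset
    noise_floor_mv: float = 0.02     # sub-waves smaller than this: ABSENT
    p_floor_mv: float = 0.012        # detection floor for P components
    qrs_detect_floor_mv: float = 0.016  # QRS sub-wave detection floor
    ring_rejection_ratio: float = 0.05  # lobes < 5 % of inner wave: artefact
    qrs_wave_window_ms: float = 90.0  # QRS sub-waves live within R ± this
    wave_margin_ms: float = 25.0     # slack around the tangent estimate
    iso_window_ms: tuple[float, float] = (60.0, 20.0)  # 40 ms ending 20 ms pre-onset
    savgol_ms: float = 24.0          # T-slope smoothing window


DEFAULT_CONFIG = DelineationConfig()


def _robust_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


# ---------------------------------------------------------------------------
# QRS bounds
# ---------------------------------------------------------------------------

def _envelope_tangent(env: np.ndarray, r: int, lo: int, hi: int,
                      side: str) -> Optional[float]:
    """Intersection of the envelope max-slope tangent with zero level."""
    denv = np.gradient(env)
    if side == "left":
        seg = slice(lo, r + 1)
        rel = int(np.argmax(denv[seg]))
    else:
        seg = slice(r, hi + 1)
        rel = int(np.argmin(denv[seg]))
    t0 = seg.start + rel
    slope = denv[t0]
    if slope == 0:
        return None
    cross = t0 - env[t0] / slope
    if not (lo - 1 <= cross <= hi + 1):
        return None  # tangent fails to intersect within the search window
    return float(cross)


def _outermost_wave_peak(x: np.ndarray, r: int, wave_window: int,
                         lo: int, hi: int, floor: float, ratio: float,
                         side: str) -> int:
    """Peak index of the outermost significant wave on one side of R.

    In the monophasic-per-side wave model (no bundle-branch morphologies),
    the waves flanking the dominant R are negative (Q and S), so bound
    candidates are sub-baseline dips above the detection floor within a
    physiological QRS extent of R — P, T and the positive ring lobes the
    band-pass leaves beside a deep narrow wave never qualify.  A dip is
    accepted only if it reaches ``ratio`` of the inner accepted wave.
    """
    if side == "left":
        a, b = max(lo, r - wave_window), min(hi, r + 2)
    else:
        a, b = max(lo, r - 2), min(hi, r + wave_window)
    seg = -x[a:b + 1]
    peaks, _ = find_peaks(seg, height=floor)
    cand = [a + int(p) for p in peaks]
    cand = [c for c in cand if (c <= r if side == "left" else c >= r)]
    cand.sort(key=lambda c: abs(c - r))  # inner to outer
    accepted = r
    for c in cand:
        if abs(x[c]) >= ratio * abs(x[accepted]):
            accepted = c
    return accepted


def _threshold_walk(x: np.ndarray, start: int, stop: int, step: int,
                    threshold: float, reference: float = 0.0,
                    stop_on_sign: bool = False) -> int:
    """March outward from ``start`` until |x − reference| < threshold
    (optionally also stopping where the signal changes sign)."""
    j = start
    sign0 = np.sign(x[start])
    while j != stop and abs(x[j] - reference) >= threshold:
        if stop_on_sign and np.sign(x[j]) != sign0:
            break
        j += step
    return j


def _settled_bound(x: np.ndarray, pk: int, stop: int, step: int,
                   noise_est: float, fs: float) -> int:
    """Boundary of the wave peaking at ``pk``: where the signal settles
    to the local post-wave level within 1 % of the wave amplitude.

    The filter leaves a slow ring/recovery plateau beside large waves;
    measuring the crossing against that local level (estimated just
    beyond a provisional sign-change stop) rather than against zero
    recovers the true wave extent for shallow and deep waves alike.
    """
    thr0 = max(ONSET_FRACTION * abs(x[pk]), 2.0 * noise_est)
    w0 = _threshold_walk(x, pk, stop, step, thr0, stop_on_sign=True)
    seg_end = w0 + step * max(1, int(round(0.020 * fs)))
    a, b = (seg_end, w0) if step < 0 else (w0, seg_end)
    a = max(0, a)
    b = min(len(x) - 1, b)
    ref = float(np.median(x[a:b + 1])) if b > a else 0.0
    amp = abs(x[pk] - ref)
    thr = max(ONSET_FRACTION * amp, 2.0 * noise_est)
    return _threshold_walk(x, pk, stop, step, thr, reference=ref)


def _flank_fit(x: np.ndarray, pk: int, step: int, lo: int, hi: int,
               core_fraction: float = 0.3) -> Optional[tuple[float, float]]:
    """(centre, σ) in samples from a log-domain Gaussian fit of the
    outer flank.

    ``log|g|`` of a Gaussian is quadratic in time, so a quadratic fit to
    the samples between the peak and the ``core_fraction`` level of the
    outer flank recovers (centre, σ) using only the wave core, which the
    filter's ring lobes barely touch.  Only outer-flank samples enter the
    fit: the inner flank belongs to the neighbouring wave.
    """
    amp = x[pk]
    s = np.sign(amp)
    js = [pk]
    j = pk
    while lo <= j + step <= hi and np.sign(x[j + step]) == s \
            and abs(x[j + step]) >= core_fraction * abs(amp) and len(js) < 14:
        j += step
        js.append(j)
    if len(js) < 5:
        return None
    t = np.asarray(js, dtype=float)
    a, b, _ = np.polyfit(t, np.log(np.abs(x[np.asarray(js)])), 2)
    if a >= -1e-12:
        return None
    sigma = np.sqrt(-1.0 / (2.0 * a))
    center = -b / (2.0 * a)
    return center, sigma


@lru_cache(maxsize=8)
def _sigma_calibration(fs: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Fitted-vs-true flank σ for the package's own band-pass.

    The 45 Hz low-pass widens the apparent flank of narrow waves and the
    1 Hz high-pass slightly narrows broad ones; passing reference
    Gaussians through the identical filter once per sampling rate gives
    an invertible fitted→true mapping used to de-bias boundary widths.
    """
    sos = butter(FILTER_ORDER, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    n = int(8 * fs)
    t_ms = np.arange(n) * 1000.0 / fs
    refs_ms = (3.0, 4.0, 5.0, 6.5, 8.0, 10.0, 12.5, 16.0, 22.0, 30.0)
    fitted_ms = []
    for s_ms in refs_ms:
        g = np.exp(-0.5 * ((t_ms - 4000.0) / s_ms) ** 2)
        y = sosfiltfilt(sos, g)
        pk = int(np.argmax(y))
        fit = _flank_fit(y, pk, +1, 0, n - 1)
        fitted_ms.append(fit[1] * 1000.0 / fs if fit else s_ms)
    return tuple(fitted_ms), refs_ms


def _debias_sigma(sigma_samples: float, fs: float) -> float:
    fitted_ms, refs_ms = _sigma_calibration(fs)
    sig_ms = sigma_samples * 1000.0 / fs
    true_ms = float(np.interp(sig_ms, fitted_ms, refs_ms))
    return true_ms * fs / 1000.0


def _flank_fit_boundary(x: np.ndarray, pk: int, step: int, lo: int, hi: int,
                        fs: float) -> Optional[float]:
    """1 % boundary (centre ± 3.035 σ̂) from the de-biased flank fit."""
    fit = _flank_fit(x, pk, step, lo, hi)
    if fit is None:
        return None
    center, sigma = fit
    return center + np.sign(step) * K_ONSET * _debias_sigma(sigma, fs)


def qrs_bounds(mb: MedianBeat, config: DelineationConfig = DEFAULT_CONFIG,
               noise_est: float = 0.0,
               ) -> tuple[Optional[int], Optional[int]]:
    """QRS onset and offset samples (None when a bound cannot be fixed)."""
    x = mb.beat - mb.isoelectric_level
    r = mb.r_index
    fs = mb.fs
    search = int(round(config.qrs_search_ms * fs / 1000.0))
    lo, hi = max(0, r - search), min(len(x) - 1, r + search)
    env = np.abs(hilbert(x))
    x_abs = np.abs(x)
    wave_window = int(round(config.qrs_wave_window_ms * fs / 1000.0))

    onset0 = _envelope_tangent(env, r, lo, hi, "left")
    offset0 = _envelope_tangent(env, r, lo, hi, "right")

    def _bound(side: str) -> Optional[int]:
        pk = _outermost_wave_peak(x, r, wave_window, lo, hi,
                                  config.qrs_detect_floor_mv,
                                  config.ring_rejection_ratio, side)
        step = -1 if side == "left" else +1
        stop = lo if side == "left" else hi
        walk = _settled_bound(x, pk, stop, step, noise_est, fs)
        # Model-based cap on how far the outermost wave can extend: the
        # de-biased log-quadratic flank fit (half-maximum extrapolation
        # as fallback).  The walk is trusted unless it overshoots the cap
        # by more than a small slack — the signature of ring/recovery
        # artefact holding the rectified signal above threshold.
        cap = _flank_fit_boundary(x, pk, step, lo, hi, fs)
        if cap is None:
            sigma = _half_width_sigma(x_abs, pk, lo, hi, step, fs)
            if sigma is not None:
                cap = pk + step * K_ONSET * sigma
        if cap is not None:
            slack = max(1, int(round(0.002 * fs)))
            cap_i = int(round(cap))
            if step * (walk - cap_i) > slack:
                walk = cap_i
        return walk

    onset = _bound("left") if onset0 is not None else None
    offset = _bound("right") if offset0 is not None else None
    if onset is not None and not onset < r:
        onset = None
    if offset is not None and not offset > r:
        offset = None
    return onset, offset


# ---------------------------------------------------------------------------
# QRS wave labelling
# ---------------------------------------------------------------------------

def _segments(x: np.ndarray, lo: int, hi: int) -> list[tuple[int, int, int]]:
    """(start, end, sign) runs of constant sign in x[lo:hi+1]; zeros merge
    with the following run."""
    s = np.sign(x[lo:hi + 1]).astype(int)
    # treat exact zeros as continuation of the previous sign
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    out = []
    start = 0
    for i in range(1, len(s)):
        if s[i] != s[start]:
            out.append((lo + start, lo + i - 1, int(s[start])))
            start = i
    out.append((lo + start, lo + len(s) - 1, int(s[start])))
    return out


def label_qrs_waves(mb: MedianBeat, qrs_onset: int, qrs_offset: int,
                    config: DelineationConfig = DEFAULT_CONFIG) -> dict:
    """Label sub-waves of the complex by baseline crossings and polarity.

    The dominant supra-baseline wave is R; a significant negative wave
    before it is Q, after it S.  With no supra-baseline wave the complex
    is taken as QS: the first sub-baseline wave is Q (dominant-polarity
    rule).  Sub-waves with extremum below the 20 µV noise floor are
    ABSENT (None).
    """
    x = mb.beat - mb.isoelectric_level
    segs = _segments(x, qrs_onset, qrs_offset)
    sig = []
    for a, b, sgn in segs:
        seg = x[a:b + 1]
        j = a + int(np.argmax(seg) if sgn > 0 else np.argmin(seg))
        if abs(x[j]) >= config.qrs_detect_floor_mv:
            sig.append({"start": a, "end": b, "sign": sgn, "peak": j})
    out = {"q_peak": None, "r_peak": None, "s_peak": None,
           "q_end": None, "waves": sig}
    pos = [w for w in sig if w["sign"] > 0]
    if pos:
        rw = max(pos, key=lambda w: x[w["peak"]])
        out["r_peak"] = rw["peak"]
        before = [w for w in sig if w["sign"] < 0 and w["peak"] < rw["peak"]]
        after = [w for w in sig if w["sign"] < 0 and w["peak"] > rw["peak"]]
        if before:
            qw = before[-1]
            out["q_peak"] = qw["peak"]
            out["q_end"] = qw["end"]
        if after:
            out["s_peak"] = after[0]["peak"]
    else:
        neg = [w for w in sig if w["sign"] < 0]
        if neg:
            out["q_peak"] = neg[0]["peak"]
            out["q_end"] = neg[0]["end"]
    return out


# ---------------------------------------------------------------------------
# P wave
# ---------------------------------------------------------------------------

def _half_width_sigma(x_abs: np.ndarray, peak: int, lo: int, hi: int,
                      direction: int, fs: float) -> Optional[float]:
    """Gaussian σ (samples) from the half-maximum crossing on one flank."""
    half = 0.5 * x_abs[peak]
    j = peak
    while lo <= j + direction <= hi and x_abs[j] >= half:
        j += direction
    if x_abs[j] >= half:
        return None  # flank truncated by the window
    # linear interpolation between j and j-direction
    x0, x1 = x_abs[j - direction], x_abs[j]
    frac = (x0 - half) / (x0 - x1) if x1 != x0 else 0.0
    dist = abs(j - direction - peak) + frac
    return dist / HALF_MAX_SIGMA


def p_wave_delineate(mb: MedianBeat, qrs_onset: int,
                     config: DelineationConfig = DEFAULT_CONFIG) -> dict:
    """P-wave components in the window before QRS onset.

    The positive component is the supra-baseline wave containing the
    window maximum; a following sub-baseline wave is the negative
    terminal component.  Outer boundaries are Gaussian-width
    extrapolations (peak ∓ 3.035 σ̂, σ̂ from the outer-flank half-maximum
    width); the component boundary is the baseline crossing between the
    two peaks.
    """
    x = mb.beat - mb.isoelectric_level
    fs = mb.fs
    w0 = max(0, qrs_onset - int(round(config.p_window_ms[0] * fs / 1000.0)))
    w1 = max(w0 + 2, qrs_onset - int(round(config.p_window_ms[1] * fs / 1000.0)))
    out = {"p_onset": None, "p_pos_peak": None, "p_pos_end": None,
           "p_neg_peak": None, "p_offset": None}
    seg = x[w0:w1 + 1]
    if len(seg) < 3:
        return out
    imax = w0 + int(np.argmax(seg))
    if x[imax] < config.p_floor_mv:
        return out
    out["p_pos_peak"] = imax
    x_abs = np.abs(x)
    sigma_l = _half_width_sigma(x_abs, imax, w0, w1, -1, fs)
    if sigma_l is not None:
        out["p_onset"] = max(w0, int(round(imax - K_ONSET * sigma_l)))

    # baseline crossing after the positive peak
    after = x[imax:w1 + 1]
    neg_idx = np.nonzero(after <= 0)[0]
    if len(neg_idx):
        cross = imax + int(neg_idx[0])
        tail = x[cross:w1 + 1]
        imin = cross + int(np.argmin(tail))
        if -x[imin] >= config.p_floor_mv:
            out["p_pos_end"] = cross
            out["p_neg_peak"] = imin
            sigma_r = _half_width_sigma(x_abs, imin, cross,
                                        min(len(x) - 1, qrs_onset - 1), +1, fs)
            if sigma_r is not None:
                out["p_offset"] = min(qrs_onset - 1,
                                      int(round(imin + K_ONSET * sigma_r)))
            return out
    # monophasic positive P: right boundary by extrapolation too
    sigma_r = _half_width_sigma(x_abs, imax, w0,
                                min(len(x) - 1, qrs_onset - 1), +1, fs)
    if sigma_r is not None:
        end = min(qrs_onset - 1, int(round(imax + K_ONSET * sigma_r)))
        out["p_pos_end"] = end
        out["p_offset"] = end
    return out


# ---------------------------------------------------------------------------
# T wave
# ---------------------------------------------------------------------------

def t_delineate(mb: MedianBeat, qrs_offset: int,
                config: DelineationConfig = DEFAULT_CONFIG,
                baseline: Optional[np.ndarray] = None) -> dict:
    """T peak, tangent-method T end, and the mirrored T onset.

    ``baseline`` optionally supplies a per-sample isoelectric line (e.g.
    the RR-fundamental fit); by default the scalar level is used.  An
    inverted T is handled by reflection: the beat is flipped to upright
    and the same rule applied.
    """
    base = np.full(len(mb.beat), mb.isoelectric_level) if baseline is None \
        else baseline
    x = mb.beat - base
    fs = mb.fs
    w0 = min(len(x) - 2, qrs_offset + int(round(config.t_window_ms[0] * fs / 1000.0)))
    w1 = min(len(x) - 1, qrs_offset + int(round(config.t_window_ms[1] * fs / 1000.0)))
    out = {"t_onset": None, "t_peak": None, "t_end": None}
    if w1 - w0 < 5:
        return out
    seg = x[w0:w1 + 1]
    ipk = w0 + int(np.argmax(np.abs(seg)))
    sign = 1.0 if x[ipk] >= 0 else -1.0
    if abs(x[ipk]) < config.noise_floor_mv:
        return out
    out["t_peak"] = ipk

    y = sign * x
    win = int(round(config.savgol_ms * fs / 1000.0)) | 1  # odd
    win = max(win, 5)
    ys = savgol_filter(y, win, 2)
    dy = savgol_filter(y, win, 2, deriv=1, delta=1.0)  # per sample

    # The slope extremum must sit on the T limb proper (above 30 % of
    # the peak), not on residual QRS ring or baseline ripple.
    core = 0.3 * ys[ipk]
    down = np.arange(ipk, w1 + 1)
    down = down[ys[down] >= core]
    if len(down):
        i0 = int(down[np.argmin(dy[down])])
        if dy[i0] < 0:
            cross = i0 - ys[i0] / dy[i0]
            if i0 <= cross <= len(x) - 1:
                out["t_end"] = int(round(cross))
    up = np.arange(w0, ipk + 1)
    up = up[ys[up] >= core]
    if len(up):
        i1 = int(up[np.argmax(dy[up])])
        if dy[i1] > 0:
            cross = i1 - ys[i1] / dy[i1]
            if 0 <= cross <= i1:
                out["t_onset"] = int(round(cross))
    return out


def t_end(mb: MedianBeat, qrs_offset: int,
          config: DelineationConfig = DEFAULT_CONFIG) -> Optional[int]:
    """Tangent-method T end sample (convenience wrapper)."""
    return t_delineate(mb, qrs_offset, config)["t_end"]


# ---------------------------------------------------------------------------
# Whole-beat orchestration
# ---------------------------------------------------------------------------

def _rr_fundamental_baseline(x: np.ndarray, fs: float, rr_ms: float,
                             quiet: np.ndarray) -> np.ndarray:
    """Fit offset + the RR fundamental to the quiet samples.

    The high-pass attenuates the beat train's RR fundamental (severely
    so when the heart rate sits below the 1 Hz cutoff), leaving a slow
    periodic tilt over the median beat.  Only the fundamental is fitted:
    higher harmonics pass the filter essentially intact, and extra terms
    make the fit ill-conditioned on the narrow isoelectric support.  If
    the fitted curve still swings far beyond the level variation seen in
    the quiet windows themselves, the fit is rejected in favour of a
    constant level.
    """
    n = len(x)
    t = np.arange(n) / fs
    omega = 2.0 * np.pi * 1000.0 / rr_ms
    design = np.column_stack([np.ones(n), np.cos(omega * t),
                              np.sin(omega * t)])
    coef, *_ = np.linalg.lstsq(design[quiet], x[quiet], rcond=None)
    baseline = design @ coef
    level = float(np.median(x[quiet]))
    quiet_span = float(np.ptp(x[quiet]))
    if np.ptp(baseline) > 3.0 * quiet_span + 1e-9:
        return np.full(n, level)
    return baseline


def delineate_beat(mb: MedianBeat, rr_ms: Optional[float] = None,
                   config: DelineationConfig = DEFAULT_CONFIG,
                   ) -> tuple[LeadFiducials, MedianBeat]:
    """Delineate one median beat; returns fiducials and the baseline-
    corrected beat whose ``isoelectric_level`` is final.

    Two passes: provisional bounds locate the PR and TP isoelectric
    segments, the RR-fundamental baseline (plus offset) is fitted there
    and removed, and the full fiducial set is measured on the corrected
    beat.  The final isoelectric level is the median of the 40 ms window
    ending 20 ms before QRS onset.
    """
    fs = mb.fs
    r = mb.r_index
    n = len(mb.beat)

    def span(lo_ms: float, hi_ms: float, ref: int) -> tuple[int, int]:
        a = max(0, ref + int(round(lo_ms * fs / 1000.0)))
        b = min(n, ref + int(round(hi_ms * fs / 1000.0)))
        return a, max(a + 1, b)

    # Fixed quiet (isoelectric) windows: start of the beat window
    # (before any P activity), the PR segment, and the TP segment.
    quiet = np.zeros(n, dtype=bool)
    for a, b in (span(-mb.pre_ms, -mb.pre_ms + 40.0, r),
                 span(-75.0, -55.0, r),
                 span(mb.post_ms - 90.0, mb.post_ms - 10.0, r)):
        quiet[a:b] = True
    if rr_ms is not None and quiet.sum() >= 10:
        baseline = _rr_fundamental_baseline(mb.beat, fs, rr_ms, quiet)
    else:
        baseline = np.full(n, float(np.median(mb.beat[quiet])))
    y = mb.beat - baseline
    noise_est = _robust_sd(y[quiet])

    corrected = dataclasses.replace(mb, beat=y, isoelectric_level=0.0)
    onset, offset = qrs_bounds(corrected, config, noise_est=noise_est)
    # Final isoelectric reference: 40 ms window ending 20 ms before onset.
    if onset is not None:
        a, b = span(-config.iso_window_ms[0], -config.iso_window_ms[1], onset)
        iso = float(np.median(y[a:b]))
    else:
        a, b = span(-75.0, -55.0, r)
        iso = float(np.median(y[a:b]))
    corrected = dataclasses.replace(corrected, isoelectric_level=iso)

    fid = LeadFiducials(r_peak=r, qrs_onset=onset, qrs_offset=offset)
    if onset is not None and offset is not None:
        waves = label_qrs_waves(corrected, onset, offset, config)
        fid.q_peak = waves["q_peak"]
        fid.q_end = waves["q_end"]
        fid.s_peak = waves["s_peak"]
        if waves["r_peak"] is not None:
            fid.r_peak = waves["r_peak"]
        else:
            fid.r_peak = None  # QS complex: no positive deflection
        p = p_wave_delineate(corrected, onset, config)
        for k, v in p.items():
            setattr(fid, k, v)
        t = t_delineate(corrected, offset, config)
        for k, v in t.items():
            setattr(fid, k, v)
    return fid, corrected
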