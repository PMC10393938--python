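"""Synthetic 12-lead ECG and cohort generation.

The beat model is a sum of Gaussian bumps (Ppos, Pneg, Q, R, S, T), one
set per lead via per-wave lead-scaling vectors, repeated at a fixed RR
interval.  Gaussians make every fiducial analytic: peaks sit at the wave
centres, wave onsets/offsets at the 1 %-of-amplitude crossing
(``c ± 3.035 σ``), and the tangent-method T end has the closed form
``c + 2 σ`` (tangent at the inflection ``c + σ``).  That is the whole
point of the fixture — delineation error is measurable sample-accurately
— at the price of realism (no QRS notching, no rate-adaptive intervals).

The cohort generator draws clinical covariates with the marginal
structure of a middle-aged community imaging cohort and assigns the LVH
label from a logistic model in QRS amplitude and systolic blood
pressure, with the intercept calibrated by bisection to hit a target
prevalence (default 1.5 %).  Each record also carries template-implied
per-lead ECG biomarkers (the "fast path"), so cohort-scale modelling
experiments do not require waveform synthesis; `beat_template_for`
returns the matching waveform template for any record so the two paths
can be cross-checked.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import (
    LEADS,
    WAVES,
    ConfigurationError,
    EcgRecord,
    FiducialTruth,
)
from . import biomarkers as bm

# Wave boundary convention: onset/offset at 1% of the wave's amplitude.
ONSET_FRACTION = 0.01
K_ONSET = float(np.sqrt(2.0 * np.log(1.0 / ONSET_FRACTION)))  # ≈ 3.035

# Waves with per-lead amplitude below this are treated as absent.
PRESENCE_FLOOR_MV = 0.02
# P components are smaller than QRS waves; they use a lower floor
# (matching the delineator's detection floor).
P_PRESENCE_FLOOR_MV = 0.012

CENTRES = ("Cheadle", "Newcastle", "Reading", "Bristol")
# Proportional to the per-centre LVH counts of the centre-rotation table
# (412 / 101 / 65 split evenly over the last two).
CENTRE_PROBS = (0.713, 0.175, 0.056, 0.056)


@dataclass
class WaveSpec:
    """One Gaussian wave: amplitude (mV), centre and width (ms)."""

    amp: float
    center_ms: float
    sigma_ms: float


def _default_waves() -> dict[str, WaveSpec]:
    # Amplitudes follow the population-median single-lead values
    # (R 0.45, S −0.29, Q −0.08 mV ...); centres/widths chosen so that the
    # implied interval biomarkers land in the adult resting-ECG regime
    # (QRS ≈ 89 ms, P ≈ 108 ms, QT ≈ 384 ms at 60 bpm, T ≈ 106 ms).
    return {
        "Ppos": WaveSpec(0.045, 100.0, 12.0),
        "Pneg": WaveSpec(-0.038, 135.0, 12.0),
        "Q": WaveSpec(-0.08, 225.0, 6.5),
        "R": WaveSpec(0.45, 250.0, 9.0),
        "S": WaveSpec(-0.29, 275.0, 6.5),
        "T": WaveSpec(0.15, 535.0, 26.5),
    }


def _default_lead_scaling() -> dict[str, tuple[float, ...]]:
    # Median over the 8 leads is 1.0 for every wave, so global (median)
    # biomarkers equal the template amplitudes.  The pattern mimics the
    # normal precordial progression: deep S in V1-V2, tall R in V4-V6,
    # no Q in V1-V2, most biphasic P in V1.
    return {
        "Ppos": (0.9, 1.3, 0.7, 0.7, 1.0, 1.2, 1.1, 1.0),
        "Pneg": (0.5, 0.7, 1.6, 1.3, 1.1, 0.9, 0.8, 0.6),
        "Q": (0.8, 1.1, 0.0, 0.0, 0.7, 0.9, 1.4, 1.5),
        "R": (0.7, 1.0, 0.3, 0.6, 1.0, 1.4, 1.55, 1.3),
        "S": (0.6, 0.9, 2.2, 2.8, 1.8, 1.1, 0.7, 0.5),
        "T": (0.9, 1.1, 0.5, 0.8, 1.0, 1.3, 1.2, 1.0),
    }


@dataclass
class BeatTemplateSpec:
    """Parametric beat template for one simulated participant."""

    waves: dict[str, WaveSpec] = field(default_factory=_default_waves)
    lead_scaling: dict[str, tuple[float, ...]] = field(
        default_factory=_default_lead_scaling
    )
    rr_interval_ms: float = 1000.0
    n_beats: Optional[int] = None  # None: as many as fit the duration
    duration_s: float = 15.0
    fs: float = 500.0
    first_beat_origin_ms: float = 100.0

    def validate(self) -> None:
        for name, w in self.waves.items():
            if w.sigma_ms <= 0:
                raise ConfigurationError(f"wave {name}: sigma must be > 0")
        if self.fs <= 2 * 45.0:
            raise ConfigurationError("fs must exceed twice the 45 Hz band edge")
        if self.rr_interval_ms <= 0 or self.duration_s <= 0:
            raise ConfigurationError("rr_interval and duration must be positive")
        n = self.resolved_n_beats()
        if self.rr_interval_ms * n > self.duration_s * 1000.0:
            raise ConfigurationError("n_beats do not fit in the record duration")
        for name, sc in self.lead_scaling.items():
            if len(sc) != len(LEADS):
                raise ConfigurationError(f"lead_scaling[{name}] must have 8 entries")

    def resolved_n_beats(self) -> int:
        max_fit = int(np.floor(self.duration_s * 1000.0 / self.rr_interval_ms))
        return max_fit if self.n_beats is None else min(self.n_beats, max_fit)

    def scaled(self, qrs_factor: float = 1.0, width_factor: float = 1.0,
               rr_interval_ms: Optional[float] = None) -> "BeatTemplateSpec":
        """Return a copy with QRS amplitudes and widths rescaled."""
        waves = {}
        for name, w in self.waves.items():
            if name in ("Q", "R", "S"):
                waves[name] = WaveSpec(w.amp * qrs_factor, w.center_ms,
                                       w.sigma_ms * width_factor)
            else:
                waves[name] = dataclasses.replace(w)
        return dataclasses.replace(
            self, waves=waves,
            rr_interval_ms=self.rr_interval_ms if rr_interval_ms is None
            else rr_interval_ms,
        )


@dataclass
class NoiseSpec:
    """Additive artefact model: sinusoidal baseline wander + white noise."""

    baseline_wander_amp_mv: float = 0.1
    baseline_wander_freq_hz: float = 0.3
    white_noise_sd_mv: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_wander_amp_mv < 0 or self.white_noise_sd_mv < 0:
            raise ConfigurationError("noise amplitudes must be >= 0")
        if not (0 <= self.baseline_wander_freq_hz < 1.0):
            raise ConfigurationError(
                "baseline wander must lie below the 1 Hz filter cutoff"
            )

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(0.0, 0.3, 0.0, 0)


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

def _add_gaussian(out: np.ndarray, t_ms: np.ndarray, amp: float,
                  center_ms: float, sigma_ms: float) -> None:
    """Add amp·exp(−(t−c)²/2σ²) to *out*, restricted to ±6σ for speed."""
    dt = t_ms[1] - t_ms[0]
    lo = int(max(0, np.floor((center_ms - 6 * sigma_ms - t_ms[0]) / dt)))
    hi = int(min(len(t_ms), np.ceil((center_ms + 6 * sigma_ms - t_ms[0]) / dt) + 1))
    if hi <= lo:
        return
    seg = t_ms[lo:hi]
    out[lo:hi] += amp * np.exp(-0.5 * ((seg - center_ms) / sigma_ms) ** 2)


def _lead_wave_amp(spec: BeatTemplateSpec, wave: str, lead_idx: int) -> float:
    w = spec.waves[wave]
    return w.amp * spec.lead_scaling[wave][lead_idx]


def _crossing_left(t: np.ndarray, x: np.ndarray, peak_idx: int,
                   threshold: float) -> float:
    """Last time left of ``peak_idx`` where |x| drops below ``threshold``."""
    seg = np.abs(x[: peak_idx + 1])
    below = np.nonzero(seg < threshold)[0]
    if len(below) == 0:
        return t[0]
    return t[below[-1]]


def _crossing_right(t: np.ndarray, x: np.ndarray, peak_idx: int,
                    threshold: float) -> float:
    seg = np.abs(x[peak_idx:])
    below = np.nonzero(seg < threshold)[0]
    if len(below) == 0:
        return t[-1]
    return t[peak_idx + below[0]]


def _zero_crossing_between(t: np.ndarray, x: np.ndarray, i0: int, i1: int) -> float:
    """Linear-interpolated sign change of x between indices i0 < i1."""
    seg = x[i0:i1 + 1]
    s = np.sign(seg)
    idx = np.nonzero(np.diff(s) != 0)[0]
    if len(idx) == 0:
        return 0.5 * (t[i0] + t[i1])
    j = i0 + idx[0]
    x0, x1 = x[j], x[j + 1]
    frac = 0.0 if x1 == x0 else x0 / (x0 - x1)
    return t[j] + frac * (t[j + 1] - t[j])


def template_truth(spec: BeatTemplateSpec,
                   dt_ms: float = 0.05) -> tuple[dict, dict]:
    """Ground-truth fiducials (ms from beat origin) per lead.

    Computed on a dense grid of the noise-free one-beat composite, using
    the package's boundary conventions: wave onset/offset at the 1 %
    amplitude crossing, sub-wave boundaries at baseline crossings, T
    onset/end at the closed-form tangent intersection ``c ∓ 2σ``.
    """
    t = np.arange(0.0, spec.rr_interval_ms, dt_ms)
    beat_ms: dict[str, dict[str, Optional[float]]] = {}
    amps: dict[str, dict[str, float]] = {}
    for li, lead in enumerate(LEADS):
        x = np.zeros_like(t)
        for wave in WAVES:
            a = _lead_wave_amp(spec, wave, li)
            w = spec.waves[wave]
            _add_gaussian(x, t, a, w.center_ms, w.sigma_ms)
        # Presence is judged on the composite: a small wave riding on a
        # larger neighbour's tail may never produce a deflection of its
        # own, in which case no delineator (and no truth) can see it.
        present: dict[str, float] = {}
        for wave in WAVES:
            a = _lead_wave_amp(spec, wave, li)
            if a == 0.0:
                continue
            w = spec.waves[wave]
            lo = max(0, int((w.center_ms - w.sigma_ms) / dt_ms))
            hi = min(len(t), int((w.center_ms + w.sigma_ms) / dt_ms) + 1)
            extremum = x[lo:hi].max() if a > 0 else x[lo:hi].min()
            floor = P_PRESENCE_FLOOR_MV if wave in ("Ppos", "Pneg") \
                else PRESENCE_FLOOR_MV
            if np.sign(extremum) == np.sign(a) and abs(extremum) >= floor:
                present[wave] = a
        amps[lead] = {wave: _lead_wave_amp(spec, wave, li) for wave in WAVES}
        f: dict[str, Optional[float]] = {k: None for k in (
            "p_onset", "p_pos_peak", "p_pos_end", "p_neg_peak", "p_offset",
            "qrs_onset", "q_peak", "q_end", "r_peak", "s_peak", "qrs_offset",
            "t_onset", "t_peak", "t_end")}

        def peak_idx(wave: str) -> int:
            w = spec.waves[wave]
            lo = int((w.center_ms - w.sigma_ms) / dt_ms)
            hi = int((w.center_ms + w.sigma_ms) / dt_ms) + 1
            seg = x[lo:hi]
            j = np.argmax(seg) if present[wave] > 0 else np.argmin(seg)
            return lo + int(j)

        # --- P wave -----------------------------------------------------
        if "Ppos" in present:
            ip = peak_idx("Ppos")
            f["p_pos_peak"] = t[ip]
            thr = ONSET_FRACTION * abs(present["Ppos"])
            f["p_onset"] = _crossing_left(t, x, ip, thr)
            if "Pneg" in present:
                inn = peak_idx("Pneg")
                f["p_neg_peak"] = t[inn]
                f["p_pos_end"] = _zero_crossing_between(t, x, ip, inn)
                thr_n = ONSET_FRACTION * abs(present["Pneg"])
                f["p_offset"] = _crossing_right(t, x, inn, thr_n)
            else:
                f["p_pos_end"] = _crossing_right(t, x, ip, thr)
                f["p_offset"] = f["p_pos_end"]
        # --- QRS --------------------------------------------------------
        qrs_present = [wv for wv in ("Q", "R", "S") if wv in present]
        if qrs_present:
            first, last = qrs_present[0], qrs_present[-1]
            i_first, i_last = peak_idx(first), peak_idx(last)
            f["qrs_onset"] = _crossing_left(
                t, x, i_first, ONSET_FRACTION * abs(present[first]))
            f["qrs_offset"] = _crossing_right(
                t, x, i_last, ONSET_FRACTION * abs(present[last]))
            for wv, key in (("Q", "q_peak"), ("R", "r_peak"), ("S", "s_peak")):
                if wv in present:
                    f[key] = t[peak_idx(wv)]
            if "Q" in present and "R" in present:
                f["q_end"] = _zero_crossing_between(
                    t, x, peak_idx("Q"), peak_idx("R"))
        # --- T wave -----------------------------------------------------
        if "T" in present:
            it = peak_idx("T")
            w = spec.waves["T"]
            f["t_peak"] = t[it]
            f["t_onset"] = w.center_ms - 2.0 * w.sigma_ms
            f["t_end"] = w.center_ms + 2.0 * w.sigma_ms
        beat_ms[lead] = f
    return beat_ms, amps


def generate_ecg(spec: Optional[BeatTemplateSpec] = None,
                 noise: Optional[NoiseSpec] = None,
                 record_id: str = "rec0",
                 centre: str = "") -> tuple[EcgRecord, FiducialTruth]:
    """Simulate one 8-lead record and its exact fiducial ground truth."""
    spec = spec or BeatTemplateSpec()
    noise = noise or NoiseSpec.none()
    spec.validate()
    noise.validate()

    n = int(round(spec.duration_s * spec.fs))
    t_ms = np.arange(n) * (1000.0 / spec.fs)
    n_beats = spec.resolved_n_beats()
    origins = spec.first_beat_origin_ms + spec.rr_interval_ms * np.arange(n_beats)

    sig = np.zeros((n, len(LEADS)))
    for li in range(len(LEADS)):
        x = sig[:, li]
        for wave in WAVES:
            a = _lead_wave_amp(spec, wave, li)
            if a == 0.0:
                continue
            w = spec.waves[wave]
            for o in origins:
                _add_gaussian(x, t_ms, a, o + w.center_ms, w.sigma_ms)

    rng = np.random.default_rng(noise.seed)
    if noise.baseline_wander_amp_mv > 0:
        phases = rng.uniform(0, 2 * np.pi, size=len(LEADS))
        wander = noise.baseline_wander_amp_mv * np.sin(
            2 * np.pi * noise.baseline_wander_freq_hz * (t_ms[:, None] / 1000.0)
            + phases[None, :])
        sig = sig + wander
    if noise.white_noise_sd_mv > 0:
        sig = sig + rng.normal(0.0, noise.white_noise_sd_mv, size=sig.shape)

    beat_ms, amps = template_truth(spec)
    truth = FiducialTruth(
        beat_ms=beat_ms,
        amplitudes_mv=amps,
        r_times_s=(origins + spec.waves["R"].center_ms) / 1000.0,
        rr_interval_ms=spec.rr_interval_ms,
    )
    rec = EcgRecord(signal=sig, fs=spec.fs, record_id=record_id, centre=centre)
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Generative model for the clinical cohort table.

    The LVH label follows ``p = expit(beta0 + beta_qrs·QRS + beta_sbp·SBP)``
    with ``beta0`` solved by bisection so the expected prevalence matches
    ``prevalence_target``.  ``lvh_qrs_boost`` scales the QRS template of
    labelled records (electrical remodelling: larger LV mass, larger
    voltage), which is what makes QRS amplitude the top-ranking ECG
    feature downstream.
    """

    n: int = 10_000
    prevalence_target: float = 0.015
    beta_qrs: float = 4.0       # per mV of latent QRS amplitude
    beta_sbp: float = 0.04      # per mmHg of adjusted systolic BP
    lvh_qrs_boost: float = 1.25
    lvh_qrs_widening: float = 1.09
    # Scales every secondary label-linked morphology effect (interval
    # prolongation, P/T changes, rate slowing); 0 gives a null cohort in
    # which, together with beta_qrs=beta_sbp=0 and boost 1.0, the label
    # is independent of every feature.
    lvh_effect_scale: float = 1.0
    female_fraction: float = 0.52
    centre_probs: tuple[float, ...] = CENTRE_PROBS
    lead_amp_jitter_sd: float = 0.30   # log-sd of per-record/lead QRS gain
    measurement_noise_mv: float = 0.015
    qt_lead_sd_ms: float = 18.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.prevalence_target < 1.0):
            raise ConfigurationError("prevalence_target must be in (0, 1)")
        if self.n < 100:
            raise ConfigurationError("n must be >= 100")
        if abs(sum(self.centre_probs) - 1.0) > 1e-9:
            raise ConfigurationError("centre_probs must sum to 1")


class CalibrationError(RuntimeError):
    """Prevalence target unattainable with the given coefficients."""


def calibrate_intercept(lp: np.ndarray, target: float,
                        tol: float = 1e-10, max_iter: int = 200) -> float:
    """Bisection on beta0 so that mean(expit(beta0 + lp)) == target.

    mean(expit(b0 + lp)) is strictly increasing in b0, so bisection on a
    bracketing interval converges monotonically.
    """
    lo, hi = -60.0, 60.0
    f_lo = float(np.mean(expit(lo + lp)))
    f_hi = float(np.mean(expit(hi + lp)))
    if not (f_lo <= target <= f_hi):
        raise CalibrationError(
            f"prevalence {target} unattainable (range [{f_lo:.3g}, {f_hi:.3g}])")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if float(np.mean(expit(mid + lp))) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# Per-wave lead patterns reused by the tabular fast path.
_LS = _default_lead_scaling()
_BASE = _default_waves()


def generate_cohort(spec: Optional[CohortSpec] = None) -> pd.DataFrame:
    """Draw a cohort table: clinical covariates, ECG biomarkers, label.

    Returns one row per participant.  Clinical columns mirror the raw
    study export (two BP readings, medication flags, raw cholesterol,
    LV mass in g); ``ecg_*`` columns are the template-implied biomarkers
    with measurement noise (the tabular fast path); ``qrs_amp_true`` and
    ``sbp_adj_true`` are the latent generative features; ``lvh`` is the
    binary label.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    female = rng.random(n) < spec.female_fraction
    sex = np.where(female, "F", "M")
    age = np.clip(rng.normal(64.0, 8.9, n), 40.0, 82.0)
    height = np.where(female, rng.normal(162.5, 6.2, n), rng.normal(175.5, 6.8, n))
    bmi = np.exp(rng.normal(np.log(26.0), 0.15, n))
    weight = bmi * (height / 100.0) ** 2

    sbp_adj = np.clip(rng.normal(142.0, 21.5, n), 90.0, 235.0)
    dbp_adj = np.clip(rng.normal(81.5, 11.0, n), 50.0, 135.0)
    bp_med = rng.random(n) < 0.245
    sbp_mean_raw = sbp_adj - 15.0 * bp_med
    dbp_mean_raw = dbp_adj - 10.0 * bp_med
    sbp1 = sbp_mean_raw + rng.normal(0, 3.0, n)
    sbp2 = 2 * sbp_mean_raw - sbp1
    dbp1 = dbp_mean_raw + rng.normal(0, 2.0, n)
    dbp2 = 2 * dbp_mean_raw - dbp1

    tc_adj = np.clip(rng.normal(4.65, 0.9, n), 2.5, 9.5)
    hdl = np.clip(rng.normal(1.45, 0.28, n), 0.6, 2.8)
    nonhdl_adj = np.clip(tc_adj - hdl, 0.5, None)
    lipid_med = rng.random(n) < 0.252
    total_chol = np.where(lipid_med, tc_adj * 0.73, tc_adj)
    non_hdl_chol = np.where(lipid_med, nonhdl_adj * 0.66, nonhdl_adj)

    hba1c = np.clip(rng.normal(36.0, 7.5, n), 20.0, 130.0)
    smoking = rng.choice(["never", "previous", "current"], size=n,
                         p=[0.606, 0.332, 0.062])
    alcohol = rng.choice(["never", "current"], size=n, p=[0.046, 0.954])
    centre = rng.choice(CENTRES, size=n, p=spec.centre_probs)

    # Latent QRS amplitude (peak-to-trough, mV) and the LVH label.
    qrs_amp_true = np.exp(rng.normal(np.log(0.90), 0.254, n))
    lp = spec.beta_qrs * qrs_amp_true + spec.beta_sbp * sbp_adj
    beta0 = calibrate_intercept(lp, spec.prevalence_target)
    p_lvh = expit(beta0 + lp)
    lvh = rng.random(n) < p_lvh

    # LV mass consistent with the label under the sex-specific thresholds.
    thr = np.where(female, 55.0, 70.0)
    bsa = np.sqrt(height * weight / 3600.0)
    over = 1.0 + np.abs(rng.normal(0.12, 0.10, n))
    under = 1.0 - np.clip(np.abs(rng.normal(0.25, 0.12, n)), 0.02, 0.8)
    lvmi = np.where(lvh, thr * over, thr * under)
    lv_mass = lvmi * bsa

    ecg = _fast_path_biomarkers(spec, rng, qrs_amp_true, lvh, female)

    df = pd.DataFrame({
        "record_id": [f"S{i:06d}" for i in range(n)],
        "age": age, "sex": sex, "height": height, "weight": weight,
        "sbp1": sbp1, "sbp2": sbp2, "dbp1": dbp1, "dbp2": dbp2,
        "bp_med": bp_med.astype(int), "lipid_med": lipid_med.astype(int),
        "total_chol": total_chol, "non_hdl_chol": non_hdl_chol,
        "hba1c": hba1c, "smoking": smoking, "alcohol": alcohol,
        "lv_mass": lv_mass, "centre": centre,
        "qrs_amp_true": qrs_amp_true, "sbp_adj_true": sbp_adj,
        "dbp_adj_true": dbp_adj, "beta0_calibrated": beta0,
        "lvh": lvh.astype(int),
    })
    return pd.concat([df, ecg], axis=1)


def _fast_path_biomarkers(spec: CohortSpec, rng: np.random.Generator,
                          qrs_amp_true: np.ndarray, lvh: np.ndarray,
                          female: np.ndarray) -> pd.DataFrame:
    """Template-implied biomarkers with lead gain jitter + sensor noise.

    Derived quantities (flags, QTc, PTFV1, QT dispersion) go through the
    same rule functions as the waveform path (:mod:`ecglvh.biomarkers`),
    so an index computed here is the index the pipeline would compute.
    """
    n = len(qrs_amp_true)
    scale = (qrs_amp_true / 0.90) * np.where(lvh, spec.lvh_qrs_boost, 1.0)
    eff = spec.lvh_effect_scale * lvh
    noise = spec.measurement_noise_mv

    def lead_amp(wave: str, lead: str, gain: np.ndarray) -> np.ndarray:
        base = _BASE[wave].amp * _LS[wave][LEADS.index(lead)]
        return base * gain + rng.normal(0, noise, n)

    # Per-record, per-lead multiplicative QRS gain (independent across
    # leads: electrode placement / torso geometry variation).
    g_qrs = np.exp(rng.normal(0.0, spec.lead_amp_jitter_sd, (n, len(LEADS))))

    r_leads = np.empty((n, len(LEADS)))
    s_leads = np.empty((n, len(LEADS)))
    q_leads = np.empty((n, len(LEADS)))
    for j, lead in enumerate(LEADS):
        gain = scale * g_qrs[:, j]
        r_leads[:, j] = lead_amp("R", lead, gain)
        s_leads[:, j] = lead_amp("S", lead, gain)
        q_leads[:, j] = lead_amp("Q", lead, gain) if _LS["Q"][j] > 0 else np.nan

    r_amp = np.median(r_leads, axis=1)
    s_amp = np.median(s_leads, axis=1)
    q_amp = np.nanmedian(q_leads, axis=1)
    qrs_amp = r_amp - s_amp

    rate = np.clip(rng.normal(62.0, 8.0, n) - 4.0 * eff, 40.0, 110.0)
    rr = 60000.0 / rate
    qt_global = 384.0 * np.sqrt(rr / 1000.0) + rng.normal(0, 10.0, n)
    qt_sd = spec.qt_lead_sd_ms * (1.0 + 0.3 * eff)
    qt_leads = qt_global[:, None] + rng.normal(0, 1.0, (n, len(LEADS))) * qt_sd[:, None]
    qtc = bm.bazett_qtc(qt_global, rr)
    qt_disp = bm.qt_dispersion(qt_leads)

    # dispersions follow the reference interquartile ranges (e.g. QRS
    # duration IQR 82-97 ms, ascending slope IQR 27-43 mV/s)
    qrs_dur = np.clip(89.0 * (1.0 + 0.04 * (scale - 1.0)) + 8.0 * eff
                      + rng.normal(0, 10.0, n), 60.0, 160.0)
    q_dur = np.clip(23.0 + 1.5 * eff + rng.normal(0, 2.0, n), 10.0, 50.0)

    p_pos_amp = np.clip(0.045 + 0.02 * eff + rng.normal(0, 0.03, n), 0.005, None)
    p_pos_dur = np.clip(52.0 - 4.0 * eff + rng.normal(0, 16.0, n), 20.0, None)
    p_neg_amp = -np.clip(0.038 + rng.normal(0, 0.015, n), 0.004, None)
    p_neg_dur = np.clip(56.0 + 4.0 * eff + rng.normal(0, 14.0, n), 20.0, None)
    p_dur = p_pos_dur + p_neg_dur
    # V1 terminal P component (most biphasic lead): scaling 1.6 on Pneg.
    p_neg_amp_v1 = p_neg_amp * _LS["Pneg"][LEADS.index("V1")]
    ptfv1 = bm.ptf_v1(p_neg_amp_v1, p_neg_dur)

    t_amp = np.clip(0.15 - 0.01 * eff + rng.normal(0, 0.05, n), 0.02, None)
    t_dur = np.clip(106.0 + 4.0 * eff + rng.normal(0, 10.0, n), 60.0, None)
    st_dev = np.abs(rng.normal(0.012, 0.012, n))
    asc_slope = np.clip(34.2 * scale * (1 + rng.normal(0, 0.30, n)), 5.0, None)
    desc_slope = -np.clip(53.4 * scale * (1 + rng.normal(0, 0.30, n)), 5.0, None)

    s_v1_depth = -s_leads[:, LEADS.index("V1")]
    r_v5 = r_leads[:, LEADS.index("V5")]
    r_v6 = r_leads[:, LEADS.index("V6")]
    sokolow = bm.sokolow_lyon_flag(s_v1_depth, r_v5, r_v6)
    r_avl = r_leads[:, LEADS.index("I")] - r_leads[:, LEADS.index("II")] / 2.0
    s_v3_depth = -s_leads[:, LEADS.index("V3")]
    cornell = bm.cornell_flag(np.clip(r_avl, 0.0, None), s_v3_depth,
                              np.where(female, "F", "M"))
    path_q = bm.pathological_q_flag(q_dur, np.abs(q_amp), np.abs(r_amp))

    cols = {
        "ecg_q_amp": q_amp, "ecg_r_amp": r_amp, "ecg_s_amp": s_amp,
        "ecg_qrs_amp": qrs_amp, "ecg_qrs_amp_v5": r_v5 - s_leads[:, LEADS.index("V5")],
        "ecg_q_dur": q_dur, "ecg_qrs_dur": qrs_dur,
        "ecg_asc_slope": asc_slope, "ecg_desc_slope": desc_slope,
        "ecg_p_pos_amp": p_pos_amp, "ecg_p_pos_dur": p_pos_dur,
        "ecg_p_neg_amp": p_neg_amp, "ecg_p_neg_dur": p_neg_dur,
        "ecg_p_dur": p_dur, "ecg_ptfv1": ptfv1,
        "ecg_t_amp": t_amp, "ecg_t_dur": t_dur,
        "ecg_qt": qt_global, "ecg_qtc": qtc, "ecg_qt_disp": qt_disp,
        "ecg_st_dev": st_dev, "ecg_rate": rate,
        "ecg_sokolow_flag": sokolow.astype(int),
        "ecg_cornell_flag": cornell.astype(int),
        "ecg_path_q_flag": path_q.astype(int),
    }
    return pd.DataFrame(cols)


#: Names of the tabular ECG biomarker columns emitted by generate_cohort.
ECG_FEATURES = [
    "ecg_q_amp", "ecg_r_amp", "ecg_s_amp", "ecg_qrs_amp", "ecg_qrs_amp_v5",
    "ecg_q_dur", "ecg_qrs_dur", "ecg_asc_slope", "ecg_desc_slope",
    "ecg_p_pos_amp", "ecg_p_pos_dur", "ecg_p_neg_amp", "ecg_p_neg_dur",
    "ecg_p_dur", "ecg_ptfv1", "ecg_t_amp", "ecg_t_dur", "ecg_qt", "ecg_qtc",
    "ecg_qt_disp", "ecg_st_dev", "ecg_rate", "ecg_sokolow_flag",
    "ecg_cornell_flag", "ecg_path_q_flag",
]


def beat_template_for(row: pd.Series, spec: Optional[CohortSpec] = None,
                      fs: float = 500.0) -> BeatTemplateSpec:
    """Waveform template matching one cohort row's fast-path biomarkers."""
    spec = spec or CohortSpec()
    scale = float(row["qrs_amp_true"]) / 0.90
    width = 1.0
    if int(row["lvh"]):
        scale *= spec.lvh_qrs_boost
        width = spec.lvh_qrs_widening
    rr = 60000.0 / float(row["ecg_rate"]) if "ecg_rate" in row else 1000.0
    rr = float(np.clip(rr, 600.0, 1400.0))
    base = BeatTemplateSpec(fs=fs)
    return base.scaled(qrs_factor=scale, width_factor=width, rr_interval_ms=rr)
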