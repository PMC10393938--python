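import numpy as np
import pytest

from ecglvh import synth, preprocess, delineate
from ecglvh.datatypes import LEADS


@pytest.fixture(scope="session")
def clean_record():
    """Default noise-free record with its analytic fiducial truth."""
    return synth.generate_ecg(synth.BeatTemplateSpec(), synth.NoiseSpec.none())


@pytest.fixture(scope="session")
def clean_beats(clean_record):
    """Filtered median beats + detected R peaks for the clean record."""
    rec, truth = clean_record
    filt = preprocess.bandpass_filter(rec)
    r_peaks = preprocess.detect_r_peaks(filt, "II")
    rr = preprocess.mean_rr_ms(r_peaks, rec.fs)
    beats = preprocess.median_beat(filt, r_peaks)
    return beats, r_peaks, rr, truth


@pytest.fixture(scope="session")
def clean_fiducials(clean_beats):
    """Delineation output for every lead of the clean record."""
    beats, r_peaks, rr, truth = clean_beats
    out = {}
    for lead in LEADS:
        fid, corrected = delineate.delineate_beat(beats[lead], rr_ms=rr)
        out[lead] = (fid, corrected)
    return out, truth


@pytest.fixture(scope="session")
def small_cohort():
    return synth.generate_cohort(synth.CohortSpec(n=4000, seed=11))


def landmark_error_ms(fid, mb, truth, lead, landmark, anchor_ms):
    """Measured-vs-truth landmark error in ms (None if absent)."""
    tv = truth.beat_ms[lead].get(landmark)
    mv = getattr(fid, landmark)
    if tv is None or mv is None:
        return tv, mv, None
    meas = (mv - mb.r_index) * 1000.0 / mb.fs + anchor_ms
    return tv, mv, meas - float(tv)
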