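"""Plain-text file formats for signals, cohorts and fiducials.

Signal files are one record per file: a header line ``# fs=<Hz>
leads=<comma list>`` followed by one whitespace-separated row per sample
(mV, one column per lead).  Cohort tables and biomarker tables are CSV
with the column dictionary documented in ``docs/methods.md``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EcgRecord, FiducialSet


def write_signal(path: str | Path, rec: EcgRecord) -> None:
    path = Path(path)
    header = f"# fs={rec.fs} leads={','.join(rec.lead_names)} " \
             f"record_id={rec.record_id} centre={rec.centre}"
    np.savetxt(path, rec.signal, fmt="%.6f", header=header, comments="")


def read_signal(path: str | Path) -> EcgRecord:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing '# fs=... leads=...' header")
    fields = dict(tok.split("=", 1) for tok in header[1:].split() if "=" in tok)
    signal = np.loadtxt(path, skiprows=1)
    return EcgRecord(
        signal=np.atleast_2d(signal),
        fs=float(fields["fs"]),
        lead_names=tuple(fields["leads"].split(",")),
        record_id=fields.get("record_id", path.stem),
        centre=fields.get("centre", ""),
    )


def write_cohort(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def fiducials_to_frame(fset: FiducialSet) -> pd.DataFrame:
    """Long-format export: lead, landmark, sample, ms."""
    rows = []
    for lead, fid in fset.leads.items():
        for landmark, idx in fid.as_dict().items():
            rows.append({
                "lead": lead, "landmark": landmark,
                "sample": idx,
                "ms": fset.samples_to_ms(idx),
            })
    return pd.DataFrame(rows)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
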