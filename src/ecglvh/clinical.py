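"""Clinical covariate derivation and the CMR-based LVH label.

Adjustments follow standard epidemiological practice for medication
masking: +15/+10 mmHg on systolic/diastolic BP under antihypertensive
treatment, total and non-HDL cholesterol divided by 0.73 and 0.66 under
lipid-lowering treatment.  Risk-factor flags use inclusive thresholds
(BP ≥ 130/85 mmHg, total cholesterol ≥ 5 mmol/L, HbA1c ≥ 48 mmol/mol);
the LVH label uses strict thresholds on BSA-indexed LV mass
(> 70 g/m² men, > 55 g/m² women) with the Mosteller body-surface-area
formula.  Flags are evaluated on the medication-adjusted values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BP_MED_SBP_ADJ = 15.0
BP_MED_DBP_ADJ = 10.0
TC_MED_DIVISOR = 0.73
NONHDL_MED_DIVISOR = 0.66
HYPERTENSION_SBP = 130.0
HYPERTENSION_DBP = 85.0
HYPERCHOL_TC = 5.0
DIABETES_HBA1C = 48.0
LVH_THRESHOLD_MEN = 70.0
LVH_THRESHOLD_WOMEN = 55.0


def adjust_bp(df: pd.DataFrame) -> pd.DataFrame:
    """Mean of the two readings, +15/+10 mmHg if on BP medication.

    A missing reading falls back to the available one and is flagged in
    ``bp_single_reading``.
    """
    sbp = df[["sbp1", "sbp2"]].mean(axis=1, skipna=True)
    dbp = df[["dbp1", "dbp2"]].mean(axis=1, skipna=True)
    single = df[["sbp1", "sbp2"]].isna().any(axis=1) | \
        df[["dbp1", "dbp2"]].isna().any(axis=1)
    med = df["bp_med"].astype(bool)
    return pd.DataFrame({
        "sbp_adj": sbp + BP_MED_SBP_ADJ * med,
        "dbp_adj": dbp + BP_MED_DBP_ADJ * med,
        "bp_single_reading": single.astype(int),
    }, index=df.index)


def adjust_cholesterol(df: pd.DataFrame) -> pd.DataFrame:
    """Divide total by 0.73 and non-HDL by 0.66 if on lipid medication."""
    med = df["lipid_med"].astype(bool)
    return pd.DataFrame({
        "tc_adj": np.where(med, df["total_chol"] / TC_MED_DIVISOR,
                           df["total_chol"]),
        "nonhdl_adj": np.where(med, df["non_hdl_chol"] / NONHDL_MED_DIVISOR,
                               df["non_hdl_chol"]),
    }, index=df.index)


def define_flags(derived: pd.DataFrame) -> pd.DataFrame:
    """Hypertension (≥130 or ≥85, adjusted BP), hypercholesterolaemia
    (adjusted TC ≥ 5), diabetes (HbA1c ≥ 48); all inclusive."""
    return pd.DataFrame({
        "hypertension": ((derived["sbp_adj"] >= HYPERTENSION_SBP)
                         | (derived["dbp_adj"] >= HYPERTENSION_DBP)).astype(int),
        "hypercholesterolaemia": (derived["tc_adj"] >= HYPERCHOL_TC).astype(int),
        "diabetes": (derived["hba1c"] >= DIABETES_HBA1C).astype(int),
    }, index=derived.index)


def mosteller_bsa(height_cm, weight_kg):
    """BSA = sqrt(height[cm] · weight[kg] / 3600) in m²."""
    return np.sqrt(np.asarray(height_cm) * np.asarray(weight_kg) / 3600.0)


def lvh_label(df: pd.DataFrame) -> pd.DataFrame:
    """BSA, indexed LV mass and the strict sex-specific LVH label.

    Records without LV mass get a missing (NaN) label; callers exclude
    and count them.
    """
    bsa = mosteller_bsa(df["height"], df["weight"])
    lvmi = df["lv_mass"] / bsa
    thr = np.where(df["sex"].astype(str) == "F",
                   LVH_THRESHOLD_WOMEN, LVH_THRESHOLD_MEN)
    label = (lvmi > thr).astype(float)
    label[df["lv_mass"].isna()] = np.nan
    return pd.DataFrame({"bsa": bsa, "lvm_indexed": lvmi, "lvh_cmr": label},
                        index=df.index)


def derive_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Full clinical derivation: adjusted BP/cholesterol, flags, label.

    Returns the input with the derived columns appended; the LVH label
    column is ``lvh_cmr`` (NaN where LV mass is missing).
    """
    bp = adjust_bp(df)
    chol = adjust_cholesterol(df)
    flags = define_flags(pd.concat([bp, chol, df[["hba1c"]]], axis=1))
    label = lvh_label(df)
    return pd.concat([df, bp, chol, flags, label], axis=1)


#: Clinical covariates offered to the classifiers ("clinical-only" set).
CLINICAL_FEATURES = [
    "age", "sex_male", "bmi", "sbp_adj", "dbp_adj", "tc_adj", "nonhdl_adj",
    "hba1c", "hypertension", "hypercholesterolaemia", "diabetes",
    "bp_med", "lipid_med", "smoking_current", "smoking_previous",
    "alcohol_current",
]


def encode_model_features(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the clinical covariates for modelling."""
    out = df.copy()
    out["sex_male"] = (out["sex"].astype(str) == "M").astype(int)
    out["bmi"] = out["weight"] / (out["height"] / 100.0) ** 2
    out["smoking_current"] = (out["smoking"] == "current").astype(int)
    out["smoking_previous"] = (out["smoking"] == "previous").astype(int)
    out["alcohol_current"] = (out["alcohol"] == "current").astype(int)
    return out
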