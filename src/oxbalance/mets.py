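"""Metabolic-syndrome phenotype definition.

Classifies the five NCEP-ATP III components (with the Korean waist cut-offs),
the MetS score (0-5), MetS itself (>=3 components), and diabetes, from
measured traits and medication flags.  All thresholds are inclusive on the
adverse side exactly as conventionally printed (>= for waist, triglycerides,
blood pressure and glucose; < for HDL) and are overridable via
:class:`MetSCriteria`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPONENT_COLUMNS = [
    "abdominal_obesity", "hypertriglyceridemia", "low_hdl",
    "high_blood_pressure", "high_fasting_glucose",
]

REQUIRED_TRAITS = ["sex", "waist", "triglycerides", "hdl", "sbp", "dbp",
                   "fasting_glucose"]


@dataclass(frozen=True)
class MetSCriteria:
    """NCEP-ATP III component thresholds (Korean waist cut-offs).

    ``sex`` is coded 0 = male, 1 = female throughout the package.
    """

    waist_male: float = 90.0          # cm, adverse if >=
    waist_female: float = 85.0
    triglycerides: float = 150.0      # mg/dL, adverse if >=
    hdl_male: float = 40.0            # mg/dL, adverse if <
    hdl_female: float = 50.0
    sbp: float = 130.0                # mmHg, adverse if >=
    dbp: float = 85.0
    fasting_glucose: float = 100.0    # mg/dL, adverse if >=
    n_components_required: int = 3


@dataclass(frozen=True)
class DiabetesCriteria:
    fasting_glucose: float = 126.0    # mg/dL
    ogtt_2h: float = 200.0            # mg/dL after 75 g OGTT
    hba1c: float = 6.5                # percent


def classify_components(pheno: pd.DataFrame,
                        criteria: MetSCriteria = MetSCriteria()
                        ) -> tuple[pd.DataFrame, pd.Index]:
    """Classify the five MetS components, MetS score, and MetS.

    Antihypertensive medication forces the blood-pressure component true and
    antidiabetic medication forces the glucose component true, regardless of
    the measured values.

    Returns ``(status, excluded)``: ``status`` holds complete cases only
    (five component booleans, ``mets_score``, ``mets``); ``excluded`` is the
    index of participants dropped for missing any required trait, mirroring
    a complete-case analysis.
    """
    missing_cols = [c for c in REQUIRED_TRAITS if c not in pheno.columns]
    if missing_cols:
        raise ValueError(f"phenotype table lacks required columns: "
                         f"{missing_cols}")
    complete = pheno[REQUIRED_TRAITS].notna().all(axis=1)
    excluded = pheno.index[~complete]
    if len(excluded):
        logger.info("classify_components: excluding %d participants with "
                    "missing MetS traits", len(excluded))
    df = pheno.loc[complete]

    female = df["sex"].astype(int) == 1
    waist_cut = np.where(female, criteria.waist_female, criteria.waist_male)
    hdl_cut = np.where(female, criteria.hdl_female, criteria.hdl_male)
    anti_htn = df.get("antihypertensive_med", pd.Series(0, index=df.index))
    anti_dm = df.get("antidiabetic_med", pd.Series(0, index=df.index))

    status = pd.DataFrame(index=df.index)
    status["abdominal_obesity"] = df["waist"].to_numpy() >= waist_cut
    status["hypertriglyceridemia"] = df["triglycerides"] >= criteria.triglycerides
    status["low_hdl"] = df["hdl"].to_numpy() < hdl_cut
    status["high_blood_pressure"] = ((df["sbp"] >= criteria.sbp)
                                     | (df["dbp"] >= criteria.dbp)
                                     | (anti_htn.astype(bool)))
    status["high_fasting_glucose"] = ((df["fasting_glucose"]
                                       >= criteria.fasting_glucose)
                                      | (anti_dm.astype(bool)))
    status["mets_score"] = status[COMPONENT_COLUMNS].sum(axis=1).astype(int)
    status["mets"] = status["mets_score"] >= criteria.n_components_required
    return status, excluded


def classify_diabetes(pheno: pd.DataFrame,
                      criteria: DiabetesCriteria = DiabetesCriteria()
                      ) -> pd.Series:
    """Diabetes: any of FPG >= 126, 2h-OGTT >= 200, HbA1c >= 6.5%, or
    insulin / oral antidiabetic medication.

    Missing lab values are treated as non-informative for that criterion; a
    participant with every criterion missing (and no medication flag) raises,
    since no determination is possible.
    """
    lab_cols = {"fasting_glucose": criteria.fasting_glucose,
                "ogtt_2h": criteria.ogtt_2h,
                "hba1c": criteria.hba1c}
    present = [c for c in lab_cols if c in pheno.columns]
    med_cols = [c for c in ("insulin_med", "antidiabetic_med")
                if c in pheno.columns]
    if not present and not med_cols:
        raise ValueError("no diabetes criterion available in table")

    any_info = pd.Series(False, index=pheno.index)
    result = pd.Series(False, index=pheno.index)
    for col in present:
        vals = pheno[col]
        any_info |= vals.notna()
        result |= (vals >= lab_cols[col]).fillna(False)
    for col in med_cols:
        flags = pheno[col].fillna(0).astype(bool)
        any_info |= pheno[col].notna()
        result |= flags
    if (~any_info).any():
        n_bad = int((~any_info).sum())
        raise ValueError(f"{n_bad} participants have every diabetes "
                         f"criterion missing")
    return result
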