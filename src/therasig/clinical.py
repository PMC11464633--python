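"""Clinical scores: VAS pain and HADS anxiety/depression summaries.

VAS (0-10) is recorded immediately before and after each recorded
session, one pre/post pair per session; HADS (two 0-21 subscales) is
recorded once per patient at a first (baseline) and a last timepoint,
which may be missing when a patient leaves before follow-up.  Change
scores are compared with the permutation test, and mean changes are
flagged against minimal clinically important differences (MCID):
1.4 points for VAS and 1.7 for each HADS scale.

Summary SDs use the population (N) denominator; displayed means are
rounded for reporting only, stored values are full precision.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import derive_seed, permutation_test

__all__ = [
    "MCID",
    "load_clinical_table",
    "bundled_clinical_table",
    "summarize_demographics",
    "summarize_vas",
    "summarize_hads",
    "clinical_summary_table",
]

#: minimal clinically important differences (points)
MCID = {"VAS": 1.4, "HADS": 1.7}

_SCORE_RANGES = {"vas_pre": (0, 10), "vas_post": (0, 10),
                 "hads_anxiety_first": (0, 21), "hads_anxiety_last": (0, 21),
                 "hads_depression_first": (0, 21), "hads_depression_last": (0, 21)}


def load_clinical_table(path) -> pd.DataFrame:
    """Read and validate a one-row-per-patient-session clinical TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "session", "age", "sex"} | set(_SCORE_RANGES)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table lacks columns: {sorted(missing)}")
    df["patient_id"] = df["patient_id"].astype(str).str.zfill(2)
    for col, (lo, hi) in _SCORE_RANGES.items():
        vals = df[col].dropna()
        if ((vals < lo) | (vals > hi)).any():
            raise ValueError(f"{col} outside [{lo}, {hi}]")
    if "severity" in df.columns:
        sev = df["severity"].dropna()
        if (~sev.isin([1, 2, 3])).any():
            raise ValueError("severity must be 1, 2 or 3")
    return df


def bundled_clinical_table() -> pd.DataFrame:
    """The packaged 9-patient ICU burn cohort clinical table."""
    with resources.as_file(
        resources.files("therasig").joinpath("data/burn_icu_clinical.tsv")
    ) as p:
        return load_clinical_table(Path(p))


def _per_patient(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("age", "sex", "burn_type", "severity",
                        "hads_anxiety_first", "hads_anxiety_last",
                        "hads_depression_first", "hads_depression_last")
            if c in table.columns]
    return table.groupby("patient_id", sort=True)[cols].first().reset_index()


def summarize_demographics(table: pd.DataFrame) -> dict:
    """Mean age (1 dp), age range, and sex percentages over patients."""
    pat = _per_patient(table)
    if len(pat) < 1:
        raise ValueError("no patients")
    ages = pat["age"].to_numpy(float)
    sex_counts = pat["sex"].value_counts()
    sex_pct = {s: round(100.0 * c / len(pat), 1) for s, c in sex_counts.items()}
    return {
        "n_patients": int(len(pat)),
        "mean_age": round(float(ages.mean()), 1),
        "age_range": (int(ages.min()), int(ages.max())),
        "sex_pct": sex_pct,
    }


def _desc(values: np.ndarray) -> dict:
    return {"mean": float(values.mean()),
            "sd": float(values.std(ddof=0)),
            "range": (float(values.min()), float(values.max()))}


def summarize_vas(table: pd.DataFrame, n_perm: int = 1600, seed: int = 0) -> dict:
    """Session-level VAS summary: pre, post, change, permutation p, MCID.

    Each recording session is one unit; change = post - pre.
    """
    sub = table.dropna(subset=["vas_pre", "vas_post"])
    if len(sub) < 2:
        raise ValueError("need at least 2 sessions with both VAS scores")
    pre = sub["vas_pre"].to_numpy(float)
    post = sub["vas_post"].to_numpy(float)
    change = post - pre
    res = permutation_test(pre, post, n_perm=n_perm,
                           seed=derive_seed(seed, "vas", "PRE-POST"))
    return {
        "n_sessions": int(len(sub)),
        "pre": _desc(pre), "post": _desc(post), "change": _desc(change),
        "p": res.p_value,
        "mcid_threshold": MCID["VAS"],
        "mcid_reached": bool(abs(change.mean()) >= MCID["VAS"]),
    }


def summarize_hads(table: pd.DataFrame, n_perm: int = 1600, seed: int = 0) -> dict:
    """Per-patient HADS summary for anxiety, depression, and total.

    Patients missing the last timepoint are excluded (count reported);
    change = last - first; MCID flag on |mean change| >= 1.7.
    """
    pat = _per_patient(table)
    complete = pat.dropna(subset=["hads_anxiety_last", "hads_depression_last"])
    n_excluded = len(pat) - len(complete)
    if len(complete) < 2:
        raise ValueError("need at least 2 patients with both HADS timepoints")
    out: dict = {"n_patients": int(len(complete)), "n_excluded": int(n_excluded)}
    first_total = (complete["hads_anxiety_first"] + complete["hads_depression_first"]).to_numpy(float)
    last_total = (complete["hads_anxiety_last"] + complete["hads_depression_last"]).to_numpy(float)
    scales = {
        "anxiety": (complete["hads_anxiety_first"].to_numpy(float),
                    complete["hads_anxiety_last"].to_numpy(float)),
        "depression": (complete["hads_depression_first"].to_numpy(float),
                       complete["hads_depression_last"].to_numpy(float)),
        "total": (first_total, last_total),
    }
    for name, (first, last) in scales.items():
        change = last - first
        res = permutation_test(first, last, n_perm=n_perm,
                               seed=derive_seed(seed, "hads", name))
        out[name] = {
            "first_mean": float(first.mean()),
            "last_mean": float(last.mean()),
            "first": _desc(first), "last": _desc(last), "change": _desc(change),
            "p": res.p_value,
            "mcid_threshold": MCID["HADS"],
            "mcid_reached": bool(abs(change.mean()) >= MCID["HADS"]),
        }
    return out


def clinical_summary_table(table: pd.DataFrame, n_perm: int = 1600,
                           seed: int = 0) -> pd.DataFrame:
    """Tidy clinical summary (one row per measure) for result export."""
    vas = summarize_vas(table, n_perm=n_perm, seed=seed)
    hads = summarize_hads(table, n_perm=n_perm, seed=seed)
    rows = [{
        "measure": "VAS", "n": vas["n_sessions"],
        "first_mean": vas["pre"]["mean"], "last_mean": vas["post"]["mean"],
        "change_mean": vas["change"]["mean"], "change_sd": vas["change"]["sd"],
        "p": vas["p"], "mcid_reached": vas["mcid_reached"],
    }]
    for name in ("anxiety", "depression", "total"):
        h = hads[name]
        rows.append({
            "measure": f"HADS_{name}", "n": hads["n_patients"],
            "first_mean": h["first_mean"], "last_mean": h["last_mean"],
            "change_mean": h["change"]["mean"], "change_sd": h["change"]["sd"],
            "p": h["p"], "mcid_reached": h["mcid_reached"],
        })
    return pd.DataFrame(rows)
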