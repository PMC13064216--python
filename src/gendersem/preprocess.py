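"""Derivation of the one-row-per-person analysis table from panel data.

Stages mirror a longitudinal incidence study on biennial self-reported
diagnoses: biennial responses are carried forward one wave; a person is
*prevalent* (and excluded) when their first valid diagnosis response is
already "yes", *incident* at the first wave where a no-history is followed by
a "yes", and a *non-case* otherwise; risk factors (smoking, hypertension,
diabetes) yield before-outcome flags; age is grouped into 18-34, 35-49,
50-64, 65+.  Each outcome gets its own analysis sample (a person prevalent
for stroke can still enter the migraine sample), together with an ordered
exclusion report mirroring a sample-selection flowchart.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dag import DEFAULT_INDICATORS, RISK_FACTORS

__all__ = [
    "derive_incidence",
    "derive_before_flags",
    "derive_age_group",
    "carry_forward_biennial",
    "build_analysis_table",
]

AGE_BINS = [18, 35, 50, 65]
AGE_LABELS = ["18-34", "35-49", "50-64", "65+"]

RISK_FLAG_NAMES = {"smoking": "smoke", "hypertension": "hypertension",
                   "diabetes": "diabetes"}


def derive_incidence(responses: dict[int, float]) -> tuple[str, int | None]:
    """Classify an ordered wave -> {0, 1} response series.

    Returns ``("prevalent", None)`` when the first valid response is 1,
    ``("incident", wave)`` at the first wave where a 0-history is followed by
    1, else ``("non-case", None)``.  Waves are processed in ascending order
    regardless of input ordering; missing (NaN) responses are skipped.
    """
    items = sorted(responses.items())
    valid = [(w, v) for w, v in items if v is not None and not np.isnan(v)]
    if not valid:
        raise ValueError("empty response series")
    if valid[0][1] == 1:
        return "prevalent", None
    for w, v in valid:
        if v == 1:
            return "incident", w
    return "non-case", None


def derive_before_flags(
    first_report: dict[str, int | None],
    status: str,
    incident_wave: int | None = None,
) -> dict[str, int]:
    """Binary risk-factor-before-outcome flags.

    For incident cases a flag is 1 iff the risk factor's first report wave
    strictly precedes the incident wave; for non-cases, iff the risk factor
    was ever reported before end of follow-up (keeps the flag defined for the
    whole analysis sample).
    """
    if status == "incident" and incident_wave is None:
        raise ValueError("incident case without an incident wave")
    flags = {}
    for rf, wave in first_report.items():
        if wave is None:
            flags[rf] = 0
        elif status == "incident":
            flags[rf] = int(wave < incident_wave)
        else:
            flags[rf] = 1
    return flags


def derive_age_group(age) -> str | np.ndarray:
    """Age group with closed lower bounds: [18,34], [35,49], [50,64], [65,inf)."""
    arr = np.asarray(age)
    if (arr < 18).any():
        raise ValueError("age below 18 outside the study population")
    idx = np.searchsorted(AGE_BINS, arr, side="right") - 1
    out = np.asarray(AGE_LABELS, dtype=object)[idx]
    return out if arr.ndim else str(out)


def carry_forward_biennial(
    panel: pd.DataFrame, outcomes: tuple[str, ...] = ("migraine", "stroke"),
) -> pd.DataFrame:
    """Copy each health-wave diagnosis response into the following wave.

    Only the immediately subsequent wave receives the copy, and only where it
    has no response of its own; all other values are unchanged.
    """
    out = panel.sort_values(["person_id", "wave"]).reset_index(drop=True)
    same_person = out["person_id"].eq(out["person_id"].shift(1))
    consecutive = out["wave"].eq(out["wave"].shift(1) + 1)
    for col in outcomes:
        if col not in out.columns:
            continue
        prev = out[col].shift(1)
        take = same_person & consecutive & out[col].isna() & prev.notna()
        out[col] = out[col].where(~take, prev)
    return out


def _incidence_matrix(panel: pd.DataFrame, outcome: str, health_waves):
    """Vectorized incidence classification; returns a per-person frame."""
    sub = panel[panel["wave"].isin(health_waves)]
    pivot = sub.pivot_table(index="person_id", columns="wave", values=outcome,
                            dropna=False)
    pivot = pivot.reindex(sorted(pivot.columns), axis=1)
    arr = pivot.to_numpy(dtype=float)
    wave_vals = np.asarray(pivot.columns)
    valid = ~np.isnan(arr)
    any_valid = valid.any(axis=1)
    first_valid = np.where(any_valid, valid.argmax(axis=1), -1)
    first_valid_val = np.where(
        any_valid, arr[np.arange(len(arr)), np.clip(first_valid, 0, None)], np.nan)
    ones = arr == 1
    has_one = ones.any(axis=1)
    first_one = ones.argmax(axis=1)
    status = np.full(len(arr), "non-case", dtype=object)
    status[~any_valid] = "no-valid-response"
    prevalent = any_valid & (first_valid_val == 1)
    status[prevalent] = "prevalent"
    incident = any_valid & ~prevalent & has_one
    status[incident] = "incident"
    inc_wave = np.where(incident, wave_vals[np.clip(first_one, 0, None)], -1)
    return pd.DataFrame({
        "person_id": pivot.index,
        "status": status,
        "incident_wave": inc_wave,
        "baseline_wave": np.where(
            any_valid, wave_vals[np.clip(first_valid, 0, None)], -1),
    })


def build_analysis_table(
    panel: pd.DataFrame,
    outcome: str,
    health_waves=(2011, 2013, 2015, 2017, 2019, 2021),
    collapse: str = "first_health_wave",
    min_age: int = 18,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the per-person analysis table for one outcome.

    Applies, in order: valid-response filter, prevalent exclusion, adult
    filter.  Time-varying indicator values are collapsed to the value at the
    person's baseline (first valid health-assessment) wave, or to the
    person-mean over waves with ``collapse="mean"``.  Returns the table and an
    exclusion report whose counts sum to input minus output persons.
    """
    if collapse not in ("first_health_wave", "mean"):
        raise ValueError(f"unknown collapse rule {collapse!r}")
    inc = _incidence_matrix(panel, outcome, health_waves)
    n_input = inc.shape[0]
    report_steps = []
    keep = inc["status"] != "no-valid-response"
    report_steps.append({"step": "no valid diagnosis response",
                         "excluded": int((~keep).sum())})
    inc = inc[keep]
    prev = inc["status"] == "prevalent"
    report_steps.append({"step": f"prevalent {outcome}",
                         "excluded": int(prev.sum())})
    inc = inc[~prev]

    base = inc.set_index("person_id")
    panel_idx = panel.set_index(["person_id", "wave"]).sort_index()
    base_rows = panel_idx.loc[
        list(zip(base.index, base["baseline_wave"]))].reset_index()

    adult = base_rows["age"] >= min_age
    report_steps.append({"step": f"age below {min_age} at baseline",
                         "excluded": int((~adult).sum())})
    base_rows = base_rows[adult.to_numpy()]
    base = base.loc[base_rows["person_id"].to_numpy()]

    tab = pd.DataFrame({"person_id": base.index.to_numpy()})
    tab["sex"] = base_rows["sex"].to_numpy()
    tab["sex_binary"] = (tab["sex"] == "female").astype(float)
    tab["age"] = base_rows["age"].to_numpy(dtype=float)
    tab["age10"] = tab["age"] / 10.0
    tab["age_group"] = derive_age_group(tab["age"].to_numpy())
    tab["immigration"] = base_rows["immigration"].to_numpy()
    tab["imm_indirect"] = (tab["immigration"] == "indirect").astype(float)
    tab["imm_direct"] = (tab["immigration"] == "direct").astype(float)
    tab["east"] = base_rows["east"].to_numpy(dtype=float)
    partner = base_rows["partner"]
    tab["partner"] = pd.to_numeric(partner, errors="coerce").to_numpy(dtype=float)
    children = base_rows["children"]
    tab["children"] = children.map(
        {"none": 0.0, "single": 1.0, "multiple": 2.0}).to_numpy(dtype=float)
    tab["sexual_orientation"] = base_rows["sexual_orientation"].map(
        {"probably heterosexual": 0.0, "probably bi- or homosexual": 1.0}
    ).to_numpy(dtype=float)
    if "weight" in base_rows:
        tab["weight"] = base_rows["weight"].to_numpy(dtype=float)

    if collapse == "first_health_wave":
        for ind in DEFAULT_INDICATORS:
            if ind in base_rows:
                tab[ind] = base_rows[ind].to_numpy(dtype=float)
    else:
        means = panel.groupby("person_id")[
            [i for i in DEFAULT_INDICATORS if i in panel.columns]].mean()
        for ind in means.columns:
            tab[ind] = means.loc[tab["person_id"], ind].to_numpy()

    # first report wave per risk factor (panel carries 0/1 per wave)
    inc_wave = base["incident_wave"].to_numpy()
    incident = (base["status"] == "incident").to_numpy()
    for rf in RISK_FACTORS:
        if rf not in panel.columns:
            continue
        reported = panel[panel[rf] == 1]
        first = reported.groupby("person_id")["wave"].min()
        fr = first.reindex(tab["person_id"]).to_numpy(dtype=float)
        has = ~np.isnan(fr)
        flag = np.where(incident, has & (fr < inc_wave), has).astype(float)
        tab[f"{RISK_FLAG_NAMES[rf]}_before_{outcome}"] = flag

    tab[f"{outcome}_incident"] = incident.astype(float)
    if tab["person_id"].duplicated().any():
        raise ValueError("duplicate person ids after collapse")

    report = {
        "outcome": outcome,
        "input_persons": n_input,
        "steps": report_steps,
        "output_persons": int(tab.shape[0]),
    }
    assert n_input - sum(s["excluded"] for s in report_steps) == tab.shape[0]
    return tab.reset_index(drop=True), report
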