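"""Time-to-event endpoint construction, follow-up summaries and pathology
risk groups.

Three endpoints, all measured in months from surgery:

* TTR — time to recurrence; death without recurrence censors.
* OS  — overall survival; death from any cause is the event.
* DFS — disease-free survival; recurrence or death, whichever first.

Median follow-up is estimated by the reverse Kaplan–Meier method (event and
censoring indicators swapped, so the "survival" curve is the censoring
distribution).

Stage-II risk groups combine primary-tumor extent and vascular/lymphatic/
perineural invasion (VELIPI): very-high risk requires both T4 and VELIPI+;
high risk is either one alone; low risk is neither.  The groups are a
disjoint partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .survival import km_estimate, km_median

__all__ = [
    "SurvivalEndpoint",
    "derive_endpoints",
    "endpoints_table",
    "median_follow_up",
    "assign_risk_group",
    "risk_group_column",
]

log = logging.getLogger("immunoscore")

ENDPOINTS = ("TTR", "OS", "DFS")
RISK_GROUPS = ("low", "high", "very_high")


@dataclass
class SurvivalEndpoint:
    patient_id: str
    endpoint: str
    time: float  # months
    event: bool


def derive_endpoints(p) -> dict[str, SurvivalEndpoint]:
    """Derive TTR, OS and DFS for one patient record.

    ``p`` is any object with attributes ``patient_id``, ``recurrence_months``,
    ``recurrence_event``, ``death_months``, ``death_event`` (a dataclass, a
    namedtuple row, or a pandas Series via attribute access).
    """
    pid = str(p.patient_id)
    death_t = p.death_months
    if death_t is None or pd.isna(death_t) or death_t < 0:
        raise ValueError(f"patient {pid}: death/censor time missing or negative")
    death_e = bool(p.death_event)
    rec_e = bool(p.recurrence_event)
    if rec_e:
        rec_t = p.recurrence_months
        if rec_t is None or pd.isna(rec_t) or rec_t < 0:
            raise ValueError(f"patient {pid}: recurrence event without valid time")
        if rec_t > death_t:
            raise ValueError(f"patient {pid}: recurrence after death/censor time")
    os_ep = SurvivalEndpoint(pid, "OS", float(death_t), death_e)
    if rec_e:
        ttr = SurvivalEndpoint(pid, "TTR", float(rec_t), True)
        dfs = SurvivalEndpoint(pid, "DFS", float(rec_t), True)
    else:
        # death without recurrence censors TTR but is a DFS event
        ttr = SurvivalEndpoint(pid, "TTR", float(death_t), False)
        dfs = SurvivalEndpoint(pid, "DFS", float(death_t), death_e)
    return {"TTR": ttr, "OS": os_ep, "DFS": dfs}


def endpoints_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """All three endpoints for every patient in a cohort table.

    Returns the ``endpoints.csv`` schema: patient_id, endpoint, time_months,
    event.
    """
    rows = []
    for p in cohort.itertuples(index=False):
        for ep in derive_endpoints(p).values():
            rows.append(
                {"patient_id": ep.patient_id, "endpoint": ep.endpoint,
                 "time_months": ep.time, "event": ep.event}
            )
    return pd.DataFrame(rows, columns=["patient_id", "endpoint", "time_months", "event"])


def median_follow_up(times, events) -> dict:
    """Median follow-up in months with 95% CI by reverse Kaplan–Meier.

    The censoring distribution is estimated by swapping event and censoring
    roles; its median is the median potential follow-up.  Undefined when no
    observation is censored.
    """
    events = [bool(e) for e in events]
    if all(events):
        raise ValueError("follow-up is undefined without censored observations")
    curve = km_estimate(times, [not e for e in events])
    return km_median(curve)


def assign_risk_group(t_stage: str, velipi) -> str:
    """Pathology risk group from tumor extent and VELIPI status.

    very_high = T4 and VELIPI+; high = exactly one of the two; low = neither.
    Patients with missing VELIPI cannot be classified.
    """
    if velipi is None or (isinstance(velipi, float) and pd.isna(velipi)):
        raise ValueError("VELIPI status missing: patient cannot be risk-classified")
    t4 = str(t_stage) == "T4"
    vel = bool(velipi)
    if t4 and vel:
        return "very_high"
    if t4 or vel:
        return "high"
    return "low"


def risk_group_column(cohort: pd.DataFrame) -> pd.Series:
    """Risk group per patient; missing VELIPI yields NA and is logged."""
    out = []
    n_missing = 0
    for p in cohort.itertuples(index=False):
        try:
            out.append(assign_risk_group(p.t_stage, p.velipi))
        except ValueError:
            out.append(pd.NA)
            n_missing += 1
    if n_missing:
        log.warning("risk grouping: %d patients omitted (missing VELIPI)", n_missing)
    return pd.Series(out, index=cohort.index, name="risk_group")
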