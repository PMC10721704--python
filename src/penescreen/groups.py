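"""Four-group classification by carrier status and symptom manifestation.

Participants are partitioned into asymptomatic/symptomatic × carrier/
non-carrier. A participant is symptomatic when at least one configured
symptom (self-reported heart failure, heart attack, infarct, treated for
arrhythmia) or ECG sign (low voltages, negative T, ventricular tachycardia,
ventricular extrasystole, atrial fibrillation) is present at any scanned
visit; carriers whose cause of death is marked cardiac are symptomatic as
well. Missing flags count as "not reported": questionnaire non-response
cannot assert disease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort

__all__ = ["SymptomConfig", "GROUPS", "assign_groups", "group_counts", "crude_or"]

GROUPS = (
    "asymptomatic_noncarrier",
    "symptomatic_noncarrier",
    "asymptomatic_carrier",
    "symptomatic_carrier",
)

DEFAULT_SYMPTOMS = ["HF", "heart_attack", "infarct", "treated_arrhythmia"]
DEFAULT_SIGNS = ["low_voltage", "negative_T", "vent_tachycardia",
                 "vent_extrasystole", "atrial_fibrillation"]


@dataclass
class SymptomConfig:
    symptoms: list[str] = field(default_factory=lambda: list(DEFAULT_SYMPTOMS))
    signs: list[str] = field(default_factory=lambda: list(DEFAULT_SIGNS))
    visits: list[int] = field(default_factory=lambda: [1, 2])
    #: substring marking a cardiac cause of death (applies to carriers only)
    cardiac_death_marker: str = "cardiac"

    @classmethod
    def from_dict(cls, d: dict) -> "SymptomConfig":
        return cls(symptoms=list(d.get("symptoms", DEFAULT_SYMPTOMS)),
                   signs=list(d.get("signs", DEFAULT_SIGNS)),
                   visits=[int(v) for v in d.get("visits", [1, 2])],
                   cardiac_death_marker=d.get("cardiac_death_marker", "cardiac"))


def assign_groups(cohort: Cohort, config: SymptomConfig | None = None
                  ) -> pd.DataFrame:
    """Assign each participant to one of the four groups.

    Returns a DataFrame indexed by participant_id with columns ``group``,
    ``carrier``, ``symptomatic`` and ``triggering_flags`` (comma-joined list
    of flag columns that fired; empty iff asymptomatic). Carriers with
    missing ECG flags at all scanned visits are classified on the remaining
    information and counted in the report rather than guessed symptomatic.
    """
    config = config or SymptomConfig()
    flag_cols = []
    for name in config.symptoms + config.signs:
        for v in config.visits:
            col = f"{name}_v{v}"
            if col not in cohort.flags.columns:
                raise KeyError(f"flag column missing from cohort: {col}")
            flag_cols.append(col)

    flags = cohort.flags[flag_cols].fillna(False)
    symptomatic = flags.any(axis=1)
    triggering = flags.apply(lambda row: ",".join(row.index[row]), axis=1)

    carrier = cohort.participants["carrier"].astype(bool)
    cod = cohort.participants["cause_of_death"].fillna("").astype(str)
    cardiac_death = carrier & cod.str.contains(config.cardiac_death_marker,
                                               case=False)
    add = cardiac_death & ~symptomatic
    triggering = triggering.where(~add, other="cause_of_death")
    symptomatic = symptomatic | cardiac_death

    group = np.where(
        carrier,
        np.where(symptomatic, "symptomatic_carrier", "asymptomatic_carrier"),
        np.where(symptomatic, "symptomatic_noncarrier", "asymptomatic_noncarrier"),
    )
    return pd.DataFrame(
        {"group": group, "carrier": carrier.astype(int),
         "symptomatic": symptomatic.astype(bool),
         "triggering_flags": triggering},
        index=cohort.participants.index,
    )


def group_counts(groups: pd.DataFrame) -> dict[str, int]:
    counts = groups["group"].value_counts()
    return {g: int(counts.get(g, 0)) for g in GROUPS}


def crude_or(groups: pd.DataFrame | dict[str, int]):
    """Crude odds ratio of being symptomatic given carrier status.

    OR = (symptomatic_carriers / asymptomatic_carriers) /
    (symptomatic_noncarriers / asymptomatic_noncarriers), with a Wald CI on
    the log scale. Zero cells trigger the Haldane–Anscombe 0.5 continuity
    correction with a warning. Returns (OR, (lo, hi), p).
    """
    counts = groups if isinstance(groups, dict) else group_counts(groups)
    a = counts["symptomatic_carrier"]
    b = counts["asymptomatic_carrier"]
    c = counts["symptomatic_noncarrier"]
    d = counts["asymptomatic_noncarrier"]
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        warnings.warn("zero cell in 2x2 table; applying 0.5 continuity correction")
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a / b) / (c / d)
    log_or = np.log(or_)
    se = np.sqrt((1.0 / cells).sum())
    z = stats.norm.ppf(0.975)
    ci = (float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se)))
    p = float(2 * stats.norm.sf(abs(log_or) / se))
    return float(or_), ci, p
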