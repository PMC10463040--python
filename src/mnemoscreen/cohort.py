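"""Patient-level cohort data model and CSV I/O.

A cohort is one row per emergency-room visit: demographic/comorbidity
covariates, tri-state symptom indicators and a binary ACS outcome.  Symptom
indicators distinguish three states — *present*, *absent* and *unrecorded* —
because a chart that never mentions a symptom does not tell us the patient
lacked it.  Internally each symptom column is a pandas nullable ``boolean``
Series: ``True`` = present, ``False`` = absent, ``pd.NA`` = unrecorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SYMPTOMS",
    "OUTCOME_POSITIVE",
    "OUTCOME_NEGATIVE",
    "COVARIATES",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "complete_case_subset",
]

#: The ten warning-symptom indicators analyzed for suspected ACS visits.
#: ``referred_pain`` is a single indicator covering neck, shoulder or jaw pain.
SYMPTOMS: tuple[str, ...] = (
    "chest_pain",
    "referred_pain",
    "sweating",
    "dyspnea",
    "palpitation",
    "nausea",
    "dizziness",
    "presyncope",
    "epigastrium_pain",
    "syncope",
)

OUTCOME_POSITIVE = "ACS"
OUTCOME_NEGATIVE = "non_ACS"

#: Optional covariate columns the pipeline knows how to stratify on.
#: Values are the recognised levels; empty string / NaN means unrecorded.
COVARIATES: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "age_group": ("<60", ">=60"),
    "bmi_group": ("underweight", "normal", "overweight", "obese"),
    "smoking": ("current", "ex", "never"),
    "hypertension": ("0", "1"),
    "dyslipidemia": ("0", "1"),
    "CAD": ("0", "1"),
    "DM": ("0", "1"),
    "CVA": ("0", "1"),
    "PAD": ("0", "1"),
}

_SYMPTOM_TOKENS = {"1": True, "0": False, "": pd.NA, "NA": pd.NA}
_SYMPTOM_TOKENS_OUT = {True: "1", False: "0"}


@dataclass
class CohortTable:
    """An ordered table of ER visits with tri-state symptoms and a binary outcome.

    Parameters
    ----------
    df
        One row per visit.  Must contain an ``outcome`` column with values
        ``"ACS"``/``"non_ACS"`` (never missing) and one nullable-boolean
        column per name in ``symptom_names``.
    symptom_names
        Ordered symptom columns; all rows share the same set.
    provenance
        Free-text source tag carried through reports.
    """

    df: pd.DataFrame
    symptom_names: tuple[str, ...] = SYMPTOMS
    provenance: str = ""

    def __post_init__(self) -> None:
        self.symptom_names = tuple(self.symptom_names)
        if len(self.df) == 0:
            raise ValueError("cohort must contain at least one row")
        if not self.symptom_names:
            raise ValueError("cohort must declare at least one symptom")
        if "outcome" not in self.df.columns:
            raise ValueError("cohort is missing the 'outcome' column")
        missing = [s for s in self.symptom_names if s not in self.df.columns]
        if missing:
            raise ValueError(f"cohort is missing symptom columns: {missing}")
        bad = ~self.df["outcome"].isin([OUTCOME_POSITIVE, OUTCOME_NEGATIVE])
        if bad.any():
            idx = self.df.index[bad][0]
            raise ValueError(
                f"row {idx}: outcome must be '{OUTCOME_POSITIVE}' or "
                f"'{OUTCOME_NEGATIVE}', got {self.df.loc[idx, 'outcome']!r}"
            )
        for s in self.symptom_names:
            if str(self.df[s].dtype) != "boolean":
                self.df[s] = self.df[s].astype("boolean")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_positive(self) -> int:
        return int((self.df["outcome"] == OUTCOME_POSITIVE).sum())

    def copy(self) -> "CohortTable":
        return replace(self, df=self.df.copy())


def _default_schema(columns: Iterable[str]) -> dict[str, str]:
    """Identity schema: every recognised column plays itself."""
    roles = {}
    for col in columns:
        if col in SYMPTOMS:
            roles[col] = f"symptom:{col}"
        elif col == "outcome":
            roles[col] = "outcome"
        elif col == "outcome_definite":
            roles[col] = "outcome_definite"
        elif col == "visit_id":
            roles[col] = "visit_id"
        elif col in COVARIATES or col == "age_years":
            roles[col] = col
    return roles


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    symptom_tokens: Mapping[str, object] | None = None,
    provenance: str | None = None,
) -> CohortTable:
    """Read and validate a cohort CSV.

    ``schema`` maps file columns to roles: ``"outcome"``, ``"visit_id"``,
    ``"symptom:<name>"``, a covariate name, or ``"outcome_definite"`` (read,
    stored, never analyzed).  With ``schema=None`` the column names themselves
    are taken as roles.  Symptom cells use the tokens ``"1"``/``"0"`` for
    present/absent and ``""`` or ``"NA"`` for unrecorded (override via
    ``symptom_tokens``).

    Raises
    ------
    ValueError
        If the outcome column is absent, an outcome cell is missing
        (rows without an outcome are rejected, not imputed), or a symptom
        cell holds an unknown token — the error names the offending cell.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema = dict(schema) if schema is not None else _default_schema(raw.columns)
    tokens = dict(_SYMPTOM_TOKENS if symptom_tokens is None else symptom_tokens)

    role_to_col: dict[str, str] = {}
    for col, role in schema.items():
        if col not in raw.columns:
            raise ValueError(f"schema column {col!r} not found in {path.name}")
        role_to_col[role] = col
    if "outcome" not in role_to_col:
        raise ValueError(f"{path.name}: no column mapped to the 'outcome' role")

    out = pd.DataFrame(index=raw.index)
    oc = role_to_col["outcome"]
    blank = raw[oc].str.strip() == ""
    if blank.any():
        # header is line 1, first data row line 2
        line = int(raw.index[blank][0]) + 2
        raise ValueError(f"{path.name} line {line}: missing outcome")
    out["outcome"] = raw[oc]

    symptom_names = []
    for role, col in role_to_col.items():
        if role.startswith("symptom:"):
            name = role.split(":", 1)[1]
            symptom_names.append(name)
            vals = []
            for i, cell in enumerate(raw[col]):
                cell = cell.strip()
                if cell not in tokens:
                    raise ValueError(
                        f"{path.name} line {i + 2}, column {col!r}: "
                        f"unknown symptom token {cell!r}"
                    )
                vals.append(tokens[cell])
            out[name] = pd.array(vals, dtype="boolean")
        elif role in ("visit_id", "outcome_definite", "age_years") or role in COVARIATES:
            out[role] = raw[col].replace("", pd.NA)

    if not symptom_names:
        raise ValueError(f"{path.name}: schema maps no symptom columns")

    table = CohortTable(
        out,
        symptom_names=tuple(symptom_names),
        provenance=provenance if provenance is not None else str(path),
    )
    return table


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV that :func:`read_cohort` maps back to the same table.

    Symptoms are encoded ``1``/``0``/``NA``; unrecorded covariates are left
    blank.  Round-tripping is the identity on all three symptom states.
    """
    path = Path(path)
    df = cohort.df.copy()
    for s in cohort.symptom_names:
        df[s] = df[s].map(_SYMPTOM_TOKENS_OUT).fillna("NA")
    # stable column order: id, covariates, symptoms, outcome(s)
    lead = [c for c in ("visit_id",) if c in df.columns]
    covs = [c for c in df.columns if c in COVARIATES or c == "age_years"]
    tail = ["outcome"] + (["outcome_definite"] if "outcome_definite" in df.columns else [])
    cols = lead + covs + list(cohort.symptom_names) + tail
    df[cols].to_csv(path, index=False)


def complete_case_subset(
    cohort: CohortTable, required: Sequence[str] | set[str]
) -> CohortTable:
    """Rows where every symptom in ``required`` is recorded (present or absent).

    This is the per-analysis complete-case restriction: each statistic is
    computed on the visits whose charts actually mention the symptoms it
    needs.  Order is preserved; an empty requirement returns the input
    unchanged.
    """
    required = list(required)
    unknown = [s for s in required if s not in cohort.symptom_names]
    if unknown:
        raise KeyError(f"unknown symptom(s): {unknown}")
    if not required:
        return cohort
    mask = pd.Series(True, index=cohort.df.index)
    for s in required:
        mask &= cohort.df[s].notna()
    sub = cohort.df.loc[mask]
    if len(sub) == 0:
        raise ValueError(f"no rows with {required} all recorded")
    return replace(cohort, df=sub)
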