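"""Comorbidity featurization from ICD-10 diagnosis and ATC dispensation records.

Two feature families are built over a 5-year lookback before therapy start
(the index date itself excluded):

* seventeen pre-specified comorbidity flags, each defined by ICD-10 and/or
  ATC code prefixes (drug dispensations proxy conditions mostly managed in
  primary care, e.g. depression/anxiety via N06A);
* a data-driven binary matrix over all ICD-10 categories (codes truncated to
  their first three characters), later filtered to categories with
  prevalence in [1%, 99%].

The shipped prefix lists are editable defaults based on standard groupings;
they are not an authoritative registry code list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._time import DAYS_PER_YEAR, LOOKBACK_DAYS

__all__ = [
    "ComorbidityDefinition",
    "ComorbidityMatrix",
    "DEFAULT_DEFINITIONS",
    "PRESPECIFIED_NAMES",
    "truncate_icd",
    "build_icd_matrix",
    "prevalence_filter",
    "flag_prespecified",
    "restrict_min_exposure",
]

_ICD_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}")


@dataclass(frozen=True)
class ComorbidityDefinition:
    name: str
    icd_patterns: tuple[str, ...] = ()
    atc_patterns: tuple[str, ...] = ()
    lookback: float = LOOKBACK_DAYS

    def __post_init__(self) -> None:
        if not self.icd_patterns and not self.atc_patterns:
            raise ValueError(f"definition {self.name!r} has no ICD or ATC patterns")


#: Default pre-specified comorbidity definitions. ICD-10/ATC prefixes follow
#: common epidemiological groupings; edit via `ComorbidityDefinition` to
#: match a specific register's criteria.
DEFAULT_DEFINITIONS: tuple[ComorbidityDefinition, ...] = (
    ComorbidityDefinition("cancer", icd_patterns=("C",)),
    ComorbidityDefinition(
        "cardiovascular_disease",
        icd_patterns=("I20", "I21", "I22", "I23", "I24", "I25", "I50"),
    ),
    ComorbidityDefinition("cerebrovascular_disease", icd_patterns=("I6",)),
    ComorbidityDefinition("dementia", icd_patterns=("F00", "F01", "F02", "F03", "G30")),
    ComorbidityDefinition(
        "depression_anxiety",
        icd_patterns=("F32", "F33", "F34", "F40", "F41"),
        atc_patterns=("N06A",),
    ),
    ComorbidityDefinition(
        "diabetes",
        icd_patterns=("E10", "E11", "E12", "E13", "E14"),
        atc_patterns=("A10",),
    ),
    ComorbidityDefinition("epilepsy", icd_patterns=("G40", "G41"), atc_patterns=("N03A",)),
    ComorbidityDefinition("headache", icd_patterns=("G44", "R51")),
    ComorbidityDefinition("hospitalized_infection", icd_patterns=("A", "B")),
    ComorbidityDefinition("hyperlipidemia", icd_patterns=("E78",), atc_patterns=("C10",)),
    ComorbidityDefinition(
        "hypertension",
        icd_patterns=("I10", "I11", "I12", "I13", "I14", "I15"),
        atc_patterns=("C02", "C03", "C07", "C08", "C09"),
    ),
    ComorbidityDefinition("inflammatory_bowel_disease", icd_patterns=("K50", "K51")),
    ComorbidityDefinition("migraine", icd_patterns=("G43",), atc_patterns=("N02C",)),
    ComorbidityDefinition("psychotic_bipolar", icd_patterns=("F2", "F30", "F31")),
    ComorbidityDefinition(
        "rheumatic_disease",
        icd_patterns=("M05", "M06", "M32", "M33", "M34", "M35", "M45"),
    ),
    ComorbidityDefinition("substance_abuse", icd_patterns=("F1",)),
    ComorbidityDefinition("traumatic_brain_injury", icd_patterns=("S06",)),
)

PRESPECIFIED_NAMES: tuple[str, ...] = tuple(sorted(d.name for d in DEFAULT_DEFINITIONS))


@dataclass
class ComorbidityMatrix:
    """Patient-by-feature binary design block.

    `prespecified` and `icd_categories` are DataFrames indexed by patient_id
    with lexicographically ordered 0/1 columns; `dropped_categories` maps a
    category to the reason it was removed by the prevalence filter.
    """

    patient_ids: list
    prespecified: pd.DataFrame
    icd_categories: pd.DataFrame
    kept_categories: list[str] = field(default_factory=list)
    dropped_categories: dict[str, str] = field(default_factory=dict)


def truncate_icd(code: str) -> str:
    """Truncate an ICD-10 code to the 3-character category level.

    Upper-cases and strips punctuation/whitespace first ("G35.9" -> "G35",
    "f900" -> "F90"). Raises ValueError on codes that do not start with a
    letter followed by two digits.
    """
    cleaned = re.sub(r"[^A-Za-z0-9]", "", str(code)).upper()
    if not _ICD_CATEGORY_RE.match(cleaned):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return cleaned[:3]


def _presence(
    records: pd.DataFrame,
    patient_ids,
    value_col: str,
    lookback: float,
) -> pd.DataFrame:
    """Records within [-lookback, 0) reduced to patient x code presence."""
    in_window = (records["t"] >= -lookback) & (records["t"] < 0)
    return records.loc[in_window, ["patient_id", value_col]]


def build_icd_matrix(
    diagnoses: pd.DataFrame,
    patient_ids,
    lookback: float = LOOKBACK_DAYS,
) -> tuple[pd.DataFrame, int]:
    """Binary patient x ICD-category matrix over the lookback window.

    A cell is 1 iff the patient has >= 1 diagnosis record with t in
    [-lookback, 0) whose code truncates to that category; any care setting
    and diagnosis role count. Returns (matrix, n_skipped_malformed).
    """
    patient_ids = list(patient_ids)
    recs = _presence(diagnoses, patient_ids, "icd_code", lookback)
    cats = []
    skipped = 0
    for code in recs["icd_code"]:
        try:
            cats.append(truncate_icd(code))
        except ValueError:
            cats.append(None)
            skipped += 1
    recs = recs.assign(category=cats).dropna(subset=["category"])
    recs = recs[recs["patient_id"].isin(set(patient_ids))]
    mat = pd.crosstab(recs["patient_id"], recs["category"]).clip(upper=1)
    mat = mat.reindex(index=patient_ids, columns=sorted(mat.columns), fill_value=0)
    mat.index.name = "patient_id"
    return mat.astype(np.int8), skipped


def prevalence_filter(
    matrix: pd.DataFrame,
    lower: float = 0.01,
    upper: float = 0.99,
) -> tuple[list[str], dict[str, str]]:
    """Split categories into kept / dropped by prevalence.

    A category is dropped iff more than ``upper`` (or less than ``lower``) of
    patients share one value, i.e. prevalence strictly outside [lower, upper];
    prevalence exactly at a bound is kept.
    """
    if matrix.shape[0] == 0:
        raise ValueError("prevalence_filter requires a non-empty matrix")
    prev = matrix.mean(axis=0)
    kept, dropped = [], {}
    for cat in matrix.columns:
        p = prev[cat]
        if p < lower:
            dropped[cat] = f"prevalence {p:.4f} < {lower}"
        elif p > upper:
            dropped[cat] = f"prevalence {p:.4f} > {upper}"
        else:
            kept.append(cat)
    return kept, dropped


def _matching_times(
    diagnoses: pd.DataFrame,
    dispensations: pd.DataFrame,
    definition: ComorbidityDefinition,
) -> pd.Series:
    """Times (days) of all records matching a definition, indexed by patient."""
    parts = []
    if definition.icd_patterns and len(diagnoses):
        codes = diagnoses["icd_code"].astype(str).str.replace(r"[^A-Za-z0-9]", "", regex=True).str.upper()
        hit = np.zeros(len(diagnoses), dtype=bool)
        for pat in definition.icd_patterns:
            hit |= codes.str.startswith(pat.upper()).to_numpy()
        parts.append(diagnoses.loc[hit, ["patient_id", "t"]])
    if definition.atc_patterns and len(dispensations):
        codes = dispensations["atc_code"].astype(str).str.upper()
        hit = np.zeros(len(dispensations), dtype=bool)
        for pat in definition.atc_patterns:
            hit |= codes.str.startswith(pat.upper()).to_numpy()
        parts.append(dispensations.loc[hit, ["patient_id", "t"]])
    if not parts:
        return pd.Series(dtype=float)
    allrec = pd.concat(parts, ignore_index=True)
    return allrec.set_index("patient_id")["t"]


def flag_prespecified(
    diagnoses: pd.DataFrame,
    dispensations: pd.DataFrame,
    patient_ids,
    definitions=DEFAULT_DEFINITIONS,
) -> pd.DataFrame:
    """Binary flags: any matching ICD or ATC record in [-lookback, 0)."""
    patient_ids = list(patient_ids)
    out = {}
    for d in sorted(definitions, key=lambda d: d.name):
        times = _matching_times(diagnoses, dispensations, d)
        in_win = times[(times >= -d.lookback) & (times < 0)]
        flagged = set(in_win.index)
        out[d.name] = np.array([1 if p in flagged else 0 for p in patient_ids], dtype=np.int8)
    mat = pd.DataFrame(out, index=patient_ids)
    mat.index.name = "patient_id"
    return mat


def restrict_min_exposure(
    diagnoses: pd.DataFrame,
    dispensations: pd.DataFrame,
    patient_ids,
    definitions=DEFAULT_DEFINITIONS,
    min_years: float = 3.0,
) -> pd.DataFrame:
    """Flags restricted to >= `min_years` of exposure at therapy start.

    A patient keeps a flag only if their earliest matching record (within the
    lookback) is at least min_years x 365.25 days before the index date.
    """
    patient_ids = list(patient_ids)
    cutoff = -min_years * DAYS_PER_YEAR
    out = {}
    for d in sorted(definitions, key=lambda d: d.name):
        times = _matching_times(diagnoses, dispensations, d)
        in_win = times[(times >= -d.lookback) & (times < 0)]
        earliest = in_win.groupby(level=0).min()
        flagged = set(earliest.index[earliest <= cutoff])
        out[d.name] = np.array([1 if p in flagged else 0 for p in patient_ids], dtype=np.int8)
    mat = pd.DataFrame(out, index=patient_ids)
    mat.index.name = "patient_id"
    return mat


def build_matrix(
    diagnoses: pd.DataFrame,
    dispensations: pd.DataFrame,
    patient_ids,
    definitions=DEFAULT_DEFINITIONS,
    lookback: float = LOOKBACK_DAYS,
    lower: float = 0.01,
    upper: float = 0.99,
) -> ComorbidityMatrix:
    """Full featurization: pre-specified flags + prevalence-filtered ICD block."""
    patient_ids = list(patient_ids)
    pre = flag_prespecified(diagnoses, dispensations, patient_ids, definitions)
    icd, _ = build_icd_matrix(diagnoses, patient_ids, lookback)
    kept, dropped = prevalence_filter(icd, lower, upper) if icd.shape[1] else ([], {})
    return ComorbidityMatrix(
        patient_ids=patient_ids,
        prespecified=pre,
        icd_categories=icd,
        kept_categories=kept,
        dropped_categories=dropped,
    )
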