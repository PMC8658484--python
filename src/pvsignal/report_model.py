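"""Case-level data model for four-table spontaneous-report databases.

Spontaneous reporting systems such as JADER distribute one release as four
comma-separated tables: DEMO (patient demographics), DRUG (drug exposures),
REAC (adverse events coded as MedDRA preferred terms) and HIST (medical
history).  This module reads that layout into a list of deduplicated
:class:`CaseReport` objects — one per patient case — writes it back out, and
applies the standard exclusion rules (drop cases with subjective age terms
such as "elderly", or with missing sex/age) that define the analysis
denominator N++.

Column names differ between releases and languages, so the reader is driven
by a logical→physical column map; the canonical logical schema is English.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("pvsignal")

# --------------------------------------------------------------------------
# vocabulary

SEXES = ("female", "male", "missing")

#: Decade age bands used for stratified reporting, plus the two tokens that
#: trigger exclusion: "subjective" (non-numeric terms such as "youth" or
#: "elderly") and "missing".
AGE_BANDS = (
    "<40",
    "40-49",
    "50-59",
    "60-69",
    "70-79",
    "80-89",
    ">=90",
    "subjective",
    "missing",
)

#: Numeric age bands in reporting order (excludes subjective/missing).
NUMERIC_AGE_BANDS = AGE_BANDS[:7]

#: Free-text age terms treated as subjective.  Real Japanese releases use
#: terms like 若年 ("youth") and 高齢 ("elderly"); fixtures use the English.
SUBJECTIVE_AGE_TERMS = frozenset(
    {"youth", "elderly", "adult", "child", "infant", "neonate", "若年", "高齢",
     "成人", "小児", "乳幼児", "新生児"}
)

#: Alternate spellings accepted for band tokens on input.
_AGE_BAND_ALIASES = {
    "≥90": ">=90",
    "90+": ">=90",
    "90-99": ">=90",
    "40–49": "40-49",
    "50–59": "50-59",
    "60–69": "60-69",
    "70–79": "70-79",
    "80–89": "80-89",
}


class DrugRole(str, Enum):
    """Causality role a reporter assigned to a drug within a case."""

    SUSPECTED = "suspected"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"
    UNKNOWN = "unknown"


_ROLE_ALIASES = {
    "suspected": DrugRole.SUSPECTED,
    "suspect": DrugRole.SUSPECTED,
    "被疑薬": DrugRole.SUSPECTED,
    "concomitant": DrugRole.CONCOMITANT,
    "併用薬": DrugRole.CONCOMITANT,
    "interacting": DrugRole.INTERACTING,
    "interaction": DrugRole.INTERACTING,
    "相互作用": DrugRole.INTERACTING,
}


def normalize_drug_name(name: str) -> str:
    """Canonical form of a generic drug name: stripped and lower-cased."""
    return str(name).strip().lower()


def parse_age_band(raw: object) -> str:
    """Map a raw age field to a canonical band token.

    Accepts integer ages, canonical/alias band tokens, subjective terms and
    blanks.  Any other non-numeric string is classified "subjective".
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return "missing"
    s = str(raw).strip()
    if not s or s.lower() in {"nan", "none"}:
        return "missing"
    s_norm = _AGE_BAND_ALIASES.get(s, s)
    if s_norm in AGE_BANDS:
        return s_norm
    low = s.lower()
    if low in SUBJECTIVE_AGE_TERMS:
        return "subjective"
    # decade notation used by JADER: "60代" ("60s")
    if low.endswith(("代", "s")) and low[:-1].isdigit():
        s = low[:-1]
    try:
        age = int(float(s))
    except ValueError:
        return "subjective"
    if age < 0:
        return "missing"
    if age < 40:
        return "<40"
    if age >= 90:
        return ">=90"
    lo = (age // 10) * 10
    return f"{lo}-{lo + 9}"


def parse_sex(raw: object) -> str:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return "missing"
    s = str(raw).strip().lower()
    if s in {"female", "f", "女性"}:
        return "female"
    if s in {"male", "m", "男性"}:
        return "male"
    return "missing"


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, slots=True)
class DrugExposure:
    """One drug row of a case: normalized generic name plus reporter role."""

    drug_name: str
    role: DrugRole = DrugRole.UNKNOWN

    def __post_init__(self) -> None:
        norm = normalize_drug_name(self.drug_name)
        if not norm:
            raise ValueError("drug_name must be non-empty")
        object.__setattr__(self, "drug_name", norm)


@dataclass(slots=True)
class CaseReport:
    """One deduplicated patient report.

    ``events`` is a set of MedDRA preferred-term codes: a PT reported several
    times within one case counts once, so downstream tallies are case counts
    rather than drug–event combination counts.
    """

    case_id: str
    sex: str = "missing"
    age_band: str = "missing"
    drugs: list[DrugExposure] = field(default_factory=list)
    events: set[str] = field(default_factory=set)
    report_year: int | None = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        self.events = set(self.events)

    def drug_names(self, roles: Iterable[DrugRole] | None = None) -> set[str]:
        """Distinct drug names, optionally restricted to the given roles."""
        if roles is None:
            return {d.drug_name for d in self.drugs}
        role_set = set(roles)
        return {d.drug_name for d in self.drugs if d.role in role_set}


@dataclass(frozen=True, slots=True)
class ExclusionRules:
    """Case-exclusion switches; all active by default."""

    drop_subjective_age: bool = True
    drop_missing_sex: bool = True
    drop_missing_age: bool = True


# --------------------------------------------------------------------------
# reading / writing the four-table layout

#: logical column -> (table, required)
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "case_id": "case_id",
    "sex": "sex",
    "age": "age",
    "report_year": "report_year",
    "drug_name": "drug_name",
    "drug_role": "drug_role",
    "pt": "pt",
}

_REQUIRED = {
    "demo": ("case_id", "sex", "age"),
    "drug": ("case_id", "drug_name"),
    "reac": ("case_id", "pt"),
}


class ColumnMapError(KeyError):
    """A logical column cannot be resolved in an input table."""


def _resolve(df: pd.DataFrame, column_map: Mapping[str, str], logical: str,
             table: str, required: bool = True) -> str | None:
    physical = column_map.get(logical, logical)
    if physical in df.columns:
        return physical
    if required:
        raise ColumnMapError(
            f"table {table!r} is missing logical column {logical!r} "
            f"(mapped to physical column {physical!r})"
        )
    return None


def read_report_tables(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    hist_path: str | Path | None = None,
    column_map: Mapping[str, str] | None = None,
    encoding: str = "utf-8",
) -> list[CaseReport]:
    """Read the four-table layout into one :class:`CaseReport` per case id.

    Drug and event rows sharing a ``case_id`` are merged into one case;
    events are deduplicated into a set.  The HIST table is accepted for
    schema completeness but carries no analysis fields.  Conflicting
    demographics across duplicate DEMO rows resolve first-wins with a logged
    warning.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    demo = pd.read_csv(demo_path, dtype=str, encoding=encoding)
    drug = pd.read_csv(drug_path, dtype=str, encoding=encoding)
    reac = pd.read_csv(reac_path, dtype=str, encoding=encoding)
    if hist_path is not None:
        pd.read_csv(hist_path, dtype=str, encoding=encoding)  # schema check only

    id_col = {t: _resolve(df, cmap, "case_id", t)
              for t, df in (("demo", demo), ("drug", drug), ("reac", reac))}
    sex_col = _resolve(demo, cmap, "sex", "demo")
    age_col = _resolve(demo, cmap, "age", "demo")
    year_col = _resolve(demo, cmap, "report_year", "demo", required=False)
    name_col = _resolve(drug, cmap, "drug_name", "drug")
    role_col = _resolve(drug, cmap, "drug_role", "drug", required=False)
    pt_col = _resolve(reac, cmap, "pt", "reac")

    cases: dict[str, CaseReport] = {}
    for row in demo.itertuples(index=False):
        row = row._asdict()
        cid = str(row[id_col["demo"]])
        year_raw = row.get(year_col) if year_col else None
        try:
            year = int(float(year_raw)) if year_raw not in (None, "") and not pd.isna(year_raw) else None
        except (TypeError, ValueError):
            year = None
        report = CaseReport(
            case_id=cid,
            sex=parse_sex(row[sex_col]),
            age_band=parse_age_band(row[age_col]),
            report_year=year,
        )
        if cid in cases:
            prev = cases[cid]
            if (prev.sex, prev.age_band) != (report.sex, report.age_band):
                logger.warning(
                    "case %s has conflicting demographics; keeping first occurrence", cid
                )
            continue
        cases[cid] = report

    for row in drug.itertuples(index=False):
        row = row._asdict()
        cid = str(row[id_col["drug"]])
        name = row[name_col]
        if name is None or (isinstance(name, float) and pd.isna(name)) or not str(name).strip():
            continue
        role_raw = row.get(role_col) if role_col else None
        role = DrugRole.UNKNOWN
        if role_raw is not None and not pd.isna(role_raw):
            role = _ROLE_ALIASES.get(str(role_raw).strip().lower(), DrugRole.UNKNOWN)
        case = cases.setdefault(cid, CaseReport(case_id=cid))
        case.drugs.append(DrugExposure(drug_name=str(name), role=role))

    for row in reac.itertuples(index=False):
        row = row._asdict()
        cid = str(row[id_col["reac"]])
        pt = row[pt_col]
        if pt is None or (isinstance(pt, float) and pd.isna(pt)) or not str(pt).strip():
            continue
        case = cases.setdefault(cid, CaseReport(case_id=cid))
        case.events.add(str(pt).strip())

    return list(cases.values())


def write_report_tables(
    cases: Sequence[CaseReport],
    out_dir: str | Path,
    column_map: Mapping[str, str] | None = None,
    encoding: str = "utf-8",
) -> dict[str, Path]:
    """Write cases back to the four-table csv layout (DEMO/DRUG/REAC/HIST).

    The emitted layout round-trips through :func:`read_report_tables`
    losslessly for every modeled field.  HIST is written with a header only.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    demo_rows = []
    drug_rows = []
    reac_rows = []
    for c in cases:
        age_out = {"subjective": "elderly", "missing": ""}.get(c.age_band, c.age_band)
        demo_rows.append({
            cmap["case_id"]: c.case_id,
            cmap["sex"]: "" if c.sex == "missing" else c.sex,
            cmap["age"]: age_out,
            cmap["report_year"]: "" if c.report_year is None else c.report_year,
        })
        for d in c.drugs:
            drug_rows.append({
                cmap["case_id"]: c.case_id,
                cmap["drug_name"]: d.drug_name,
                cmap["drug_role"]: d.role.value,
            })
        for pt in sorted(c.events):
            reac_rows.append({cmap["case_id"]: c.case_id, cmap["pt"]: pt})

    paths = {
        "demo": out / "DEMO.csv",
        "drug": out / "DRUG.csv",
        "reac": out / "REAC.csv",
        "hist": out / "HIST.csv",
    }
    pd.DataFrame(demo_rows, columns=[cmap["case_id"], cmap["sex"], cmap["age"],
                                     cmap["report_year"]]).to_csv(
        paths["demo"], index=False, encoding=encoding)
    pd.DataFrame(drug_rows, columns=[cmap["case_id"], cmap["drug_name"],
                                     cmap["drug_role"]]).to_csv(
        paths["drug"], index=False, encoding=encoding)
    pd.DataFrame(reac_rows, columns=[cmap["case_id"], cmap["pt"]]).to_csv(
        paths["reac"], index=False, encoding=encoding)
    pd.DataFrame(columns=[cmap["case_id"], "history_term"]).to_csv(
        paths["hist"], index=False, encoding=encoding)
    return paths


# --------------------------------------------------------------------------
# exclusions


def exclusion_reason(case: CaseReport, rules: ExclusionRules) -> str | None:
    """First matching exclusion reason for a case, or None if retained."""
    if rules.drop_subjective_age and case.age_band == "subjective":
        return "subjective_age"
    if rules.drop_missing_sex and case.sex == "missing":
        return "missing_sex"
    if rules.drop_missing_age and case.age_band == "missing":
        return "missing_age"
    return None


def apply_exclusions(
    cases: Sequence[CaseReport],
    rules: ExclusionRules = ExclusionRules(),
) -> tuple[list[CaseReport], Counter[str]]:
    """Partition cases into retained ones and counts of exclusions by reason.

    The retained count is the analysis-wide N++.  Removed cases are counted
    under the first matching reason (subjective age, then missing sex, then
    missing age); retained + excluded always sums to the input size.
    """
    retained: list[CaseReport] = []
    counts: Counter[str] = Counter()
    for case in cases:
        reason = exclusion_reason(case, rules)
        if reason is None:
            retained.append(case)
        else:
            counts[reason] += 1
    return retained, counts


__all__ = [
    "AGE_BANDS",
    "NUMERIC_AGE_BANDS",
    "SEXES",
    "SUBJECTIVE_AGE_TERMS",
    "CaseReport",
    "ColumnMapError",
    "DrugExposure",
    "DrugRole",
    "ExclusionRules",
    "apply_exclusions",
    "exclusion_reason",
    "normalize_drug_name",
    "parse_age_band",
    "parse_sex",
    "read_report_tables",
    "write_report_tables",
    "DEFAULT_COLUMN_MAP",
]
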