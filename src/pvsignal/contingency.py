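"""Case-based 2×2 contingency tables for drugs and drug classes.

Disproportionality analysis compares how often a target adverse event is
reported with a drug (or drug class) against the background of all other
reports.  Every count here is a count of *cases*, not of drug–event rows: a
case exposed to two members of a class contributes once to the exposed
margin, and a case with three matching PTs contributes once to the event
margin.

                 target AE   other AEs
  target drug       N11        N10       N1+
  other drugs       N01        N00       N0+
                    N+1        N+0       N++
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .report_model import CaseReport, DrugRole, NUMERIC_AGE_BANDS, normalize_drug_name

#: Default causality-role filter for the exposed margin: only drugs the
#: reporter marked as suspected count toward a drug's case tally.
DEFAULT_COUNTED_ROLES: frozenset[DrugRole] = frozenset({DrugRole.SUSPECTED})


@dataclass(frozen=True)
class DrugGroup:
    """A named set of generic drug names: one drug, or a drug class."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]):
        norm = frozenset(normalize_drug_name(m) for m in members)
        if not norm or "" in norm:
            raise ValueError(f"drug group {name!r} must have non-empty members")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", norm)

    @classmethod
    def single(cls, drug_name: str) -> "DrugGroup":
        return cls(normalize_drug_name(drug_name), [drug_name])

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "DrugGroup":
        """Read a class list from a plain-text file, one generic name per line."""
        path = Path(path)
        members = [
            line.strip() for line in path.read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls(name or path.stem, members)


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Cell counts of the case-based 2×2 table, with derived margins."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for cell in (self.n11, self.n10, self.n01, self.n00):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def n1plus(self) -> int:
        return self.n11 + self.n10

    @property
    def nplus1(self) -> int:
        return self.n11 + self.n01

    @property
    def nplusplus(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @classmethod
    def from_margins(cls, n11: int, n1plus: int, nplus1: int,
                     nplusplus: int) -> "ContingencyTable":
        """Build a table from N11 and its three margins."""
        if n11 > n1plus or n11 > nplus1:
            raise ValueError("n11 cannot exceed its margins")
        n10 = n1plus - n11
        n01 = nplus1 - n11
        n00 = nplusplus - n11 - n10 - n01
        if n00 < 0:
            raise ValueError("margins exceed the grand total")
        return cls(n11=n11, n10=n10, n01=n01, n00=n00)


def count_table(
    cases: Sequence[CaseReport],
    group: DrugGroup,
    flags: Mapping[str, bool],
    roles: frozenset[DrugRole] = DEFAULT_COUNTED_ROLES,
) -> ContingencyTable:
    """Tally the case-based 2×2 table for one drug group.

    A case sits in the exposed margin iff it has at least one exposure with a
    counted role to at least one group member — once, however many member
    drugs it took.  The four cells partition the input cases.
    """
    n11 = n10 = n01 = n00 = 0
    for c in cases:
        exposed = not group.members.isdisjoint(c.drug_names(roles))
        flagged = bool(flags.get(c.case_id, False))
        if exposed and flagged:
            n11 += 1
        elif exposed:
            n10 += 1
        elif flagged:
            n01 += 1
        else:
            n00 += 1
    return ContingencyTable(n11=n11, n10=n10, n01=n01, n00=n00)


@dataclass(frozen=True, slots=True)
class StratumSpec:
    """Which demographic axes to stratify on."""

    by_sex: bool = True
    by_age_band: bool = True

    def __post_init__(self) -> None:
        if not (self.by_sex or self.by_age_band):
            raise ValueError("at least one stratification axis is required")


def reporting_rate(n11: int, n1plus: int) -> float | None:
    """Reporting rate 100·N11/N1+ as a percentage, rounded half-up to 1 dp.

    Undefined (None) when the drug has no reported cases at all.
    """
    if n1plus == 0:
        return None
    pct = Decimal(100 * n11) / Decimal(n1plus)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def stratify_counts(
    cases: Sequence[CaseReport],
    group: DrugGroup,
    flags: Mapping[str, bool],
    spec: StratumSpec = StratumSpec(),
    roles: frozenset[DrugRole] = DEFAULT_COUNTED_ROLES,
) -> pd.DataFrame:
    """Per-stratum N11/N1+ and reporting rate for one drug group.

    Rows are Total, then the sexes, then the decade age bands, matching the
    standard demographic breakdown of a signal screen.  Each stratum row is
    :func:`count_table` restricted to that stratum.
    """
    strata: list[tuple[str, list[CaseReport]]] = [("Total", list(cases))]
    if spec.by_sex:
        for sex, label in (("female", "Female"), ("male", "Male")):
            strata.append((label, [c for c in cases if c.sex == sex]))
    if spec.by_age_band:
        for band in NUMERIC_AGE_BANDS:
            strata.append((band, [c for c in cases if c.age_band == band]))

    rows = []
    for label, sub in strata:
        t = count_table(sub, group, flags, roles)
        rows.append({
            "stratum": label,
            "n11": t.n11,
            "n1plus": t.n1plus,
            "reporting_rate": reporting_rate(t.n11, t.n1plus),
        })
    return pd.DataFrame(rows, columns=["stratum", "n11", "n1plus", "reporting_rate"])


def find_combination_cases(
    cases: Sequence[CaseReport],
    group_a: DrugGroup,
    group_b: DrugGroup,
    flags: Mapping[str, bool],
    roles: frozenset[DrugRole] | None = None,
) -> pd.DataFrame:
    """List flagged cases exposed to members of both groups.

    By default all exposure roles count: a case "in combination with" a class
    member need not have that member marked as suspected.  Rows are sorted by
    case id and list the member drugs from each group.
    """
    rows = []
    for c in cases:
        if not flags.get(c.case_id, False):
            continue
        names = c.drug_names(roles)
        in_a = sorted(group_a.members & names)
        in_b = sorted(group_b.members & names)
        if in_a and in_b:
            rows.append({
                "case_id": c.case_id,
                "sex": c.sex,
                "age_band": c.age_band,
                f"{group_a.name}_drugs": ", ".join(in_a),
                f"{group_b.name}_drugs": ", ".join(in_b),
                "report_year": c.report_year,
            })
    cols = ["case_id", "sex", "age_band", f"{group_a.name}_drugs",
            f"{group_b.name}_drugs", "report_year"]
    return pd.DataFrame(sorted(rows, key=lambda r: r["case_id"]), columns=cols)


__all__ = [
    "ContingencyTable",
    "DEFAULT_COUNTED_ROLES",
    "DrugGroup",
    "StratumSpec",
    "count_table",
    "find_combination_cases",
    "reporting_rate",
    "stratify_counts",
]
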