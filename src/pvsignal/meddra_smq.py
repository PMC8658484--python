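"""Standardized MedDRA Query (SMQ) definitions and case flagging.

An SMQ is a curated set of MedDRA preferred terms (PTs) representing one
medical condition; each term carries a narrow or broad scope.  Angioedema is
SMQ 20000024.  A case is flagged for the condition when its event set
contains at least one in-scope PT; a case with several matching PTs still
counts exactly once, so counts downstream are case counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

from .report_model import CaseReport

Scope = Literal["narrow", "broad"]
ScopeFilter = Literal["narrow_only", "narrow_and_broad"]


class SMQParseError(ValueError):
    """Malformed SMQ definition file."""


@dataclass(frozen=True)
class SMQDefinition:
    """A PT→scope mapping for one SMQ."""

    smq_id: str
    name: str
    terms: Mapping[str, Scope] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.terms:
            raise SMQParseError(f"SMQ {self.smq_id}: no terms")
        bad = {s for s in self.terms.values() if s not in ("narrow", "broad")}
        if bad:
            raise SMQParseError(f"SMQ {self.smq_id}: unknown scopes {sorted(bad)}")

    def pt_set(self, scope_filter: ScopeFilter = "narrow_and_broad") -> frozenset[str]:
        """PT codes selected by the scope filter."""
        if scope_filter == "narrow_only":
            return frozenset(pt for pt, s in self.terms.items() if s == "narrow")
        if scope_filter == "narrow_and_broad":
            return frozenset(self.terms)
        raise ValueError(f"unknown scope filter {scope_filter!r}")


def load_smq(path: str | Path) -> SMQDefinition:
    """Load an SMQ definition from a tab- or comma-separated file.

    Required columns: ``pt_code``, ``pt_name``, ``smq_id``, ``scope``.  Scope
    tokens are parsed case-insensitively.  A duplicate PT with a conflicting
    scope, or an unknown scope token, raises :class:`SMQParseError` with the
    offending line number.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    first_line = text.splitlines()[0] if text.splitlines() else ""
    delim = "\t" if "\t" in first_line else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    required = {"pt_code", "pt_name", "smq_id", "scope"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise SMQParseError(
            f"{path}: header must contain columns {sorted(required)}"
        )

    terms: dict[str, Scope] = {}
    smq_id = ""
    name = ""
    for lineno, row in enumerate(reader, start=2):
        pt = row["pt_code"].strip()
        if not pt:
            continue
        scope = row["scope"].strip().lower()
        if scope not in ("narrow", "broad"):
            raise SMQParseError(
                f"{path}:{lineno}: unknown scope token {row['scope']!r}"
            )
        if pt in terms and terms[pt] != scope:
            raise SMQParseError(
                f"{path}:{lineno}: PT {pt} already defined with scope {terms[pt]!r}"
            )
        terms[pt] = scope
        smq_id = smq_id or row["smq_id"].strip()
        name = name or row.get("smq_name", "").strip() or row["pt_name"].strip()
    if not terms:
        raise SMQParseError(f"{path}: no terms")
    return SMQDefinition(smq_id=smq_id, name=name, terms=terms)


def flag_cases(
    cases: Iterable[CaseReport],
    smq: SMQDefinition,
    scope_filter: ScopeFilter = "narrow_and_broad",
) -> dict[str, bool]:
    """Map each case id to whether the case contains an in-scope PT.

    Flagging is per case: duplicating a matching PT within a case, or adding
    further matching PTs, never changes the flag.  Both scopes are used by
    default.
    """
    pts = smq.pt_set(scope_filter)
    return {c.case_id: not pts.isdisjoint(c.events) for c in cases}


__all__ = ["SMQDefinition", "SMQParseError", "Scope", "ScopeFilter",
           "flag_cases", "load_smq"]
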