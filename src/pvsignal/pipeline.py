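"""End-to-end orchestration: read → exclude → flag → count → score → write.

:func:`run_analysis` turns a four-table reporting database plus an SMQ
definition and drug-class lists into the standard outputs of a signal
screen: a per-drug scored table, a per-class scored table, a demographic
strata table, and a listing of cases exposed to members of both classes.
:func:`score_counts` scores a single 2×2 table from its margins, which is
the vehicle for golden-value checks against published counts.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import bcpnn, contingency, meddra_smq, report_model
from .bcpnn import ICResult, PriorSpec, DEFAULT_PRIORS
from .contingency import DEFAULT_COUNTED_ROLES, DrugGroup
from .report_model import CaseReport, DrugRole, ExclusionRules

logger = logging.getLogger("pvsignal")


@dataclass
class RunConfig:
    """Validated configuration of one end-to-end run."""

    demo_path: Path
    drug_path: Path
    reac_path: Path
    smq_path: Path
    class_paths: dict[str, Path]
    hist_path: Path | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    encoding: str = "utf-8"
    scope_filter: meddra_smq.ScopeFilter = "narrow_and_broad"
    exclusion_rules: ExclusionRules = field(default_factory=ExclusionRules)
    counted_roles: frozenset[DrugRole] = DEFAULT_COUNTED_ROLES
    priors: PriorSpec = DEFAULT_PRIORS
    dash_undefined: bool = True  # render a dash for rows with no exposed cases
    out_dir: Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for attr in ("demo_path", "drug_path", "reac_path", "smq_path"):
            p = Path(getattr(self, attr))
            setattr(self, attr, p)
            if not p.exists():
                raise FileNotFoundError(f"{attr}: {p}")
        if self.hist_path is not None:
            self.hist_path = Path(self.hist_path)
            if not self.hist_path.exists():
                raise FileNotFoundError(f"hist_path: {self.hist_path}")
        if not self.class_paths:
            raise ValueError("at least one drug-class list is required")
        self.class_paths = {k: Path(v) for k, v in self.class_paths.items()}
        for name, p in self.class_paths.items():
            if not p.exists():
                raise FileNotFoundError(f"class list {name!r}: {p}")
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None,
                  base_dir: str | Path | None = None) -> "RunConfig":
        """Load a run configuration; relative paths resolve against the file."""
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        base = Path(base_dir) if base_dir else path.parent

        def rel(p):
            return base / p

        rules = ExclusionRules(**raw.get("exclusion_rules", {}))
        roles = frozenset(
            DrugRole(r) for r in raw.get("counted_roles", ["suspected"]))
        return cls(
            demo_path=rel(raw["demo"]),
            drug_path=rel(raw["drug"]),
            reac_path=rel(raw["reac"]),
            hist_path=rel(raw["hist"]) if raw.get("hist") else None,
            smq_path=rel(raw["smq"]),
            class_paths={k: rel(v) for k, v in raw["classes"].items()},
            column_map=raw.get("columns", {}),
            encoding=raw.get("encoding", "utf-8"),
            scope_filter=raw.get("scope_filter", "narrow_and_broad"),
            exclusion_rules=rules,
            counted_roles=roles,
            dash_undefined=raw.get("dash_undefined", True),
            out_dir=Path(out_dir) if out_dir else None,
            log_level=raw.get("log_level", "INFO"),
        )


@dataclass
class ResultBundle:
    """Outputs of one run, as data frames plus a run log."""

    per_drug: pd.DataFrame
    per_class: pd.DataFrame
    strata: pd.DataFrame
    combinations: pd.DataFrame
    log: dict


def score_counts(n11: int, n1plus: int, nplus1: int, nplusplus: int,
                 priors: PriorSpec = DEFAULT_PRIORS) -> ICResult:
    """Score one 2×2 table given N11 and its margins.

    Counts must be consistent (N11 within its margins, margins within N++);
    the all-prior table (0, 0, 0, 1) is degenerate but finite.
    """
    table = contingency.ContingencyTable.from_margins(
        n11, n1plus, nplus1, nplusplus)
    return bcpnn.ic_result(table, priors)


def _score_groups(cases: Sequence[CaseReport], groups: Sequence[DrugGroup],
                  flags: Mapping[str, bool],
                  roles: frozenset[DrugRole], priors: PriorSpec,
                  labels: Mapping[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for g in groups:
        t = contingency.count_table(cases, g, flags, roles)
        r = bcpnn.ic_result(t, priors)
        rows.append({
            "group_name": g.name,
            "drug_class": (labels or {}).get(g.name, g.name),
            "n11": t.n11, "n1plus": t.n1plus,
            "nplus1": t.nplus1, "nplusplus": t.nplusplus,
            "e_ic": r.e_ic, "v_ic": r.v_ic,
            "ic025": r.ic025, "ic975": r.ic975,
            "classification": r.classification.value,
        })
    return pd.DataFrame(rows)


def run_analysis(config: RunConfig) -> ResultBundle:
    """Execute the full screen and (optionally) write its output tables.

    Per-drug and per-class outputs carry the 2×2 margins, IC moments, 95%
    credible bounds and classification, with each class-total row first and
    member drugs alphabetical; the strata output is the demographic
    breakdown per class; the combination output lists flagged cases exposed
    to members of at least two classes.  The run log records N++, exclusion
    counts, the SMQ term count and content checksums of the outputs.
    """
    logging.basicConfig(level=config.log_level)
    cases = report_model.read_report_tables(
        config.demo_path, config.drug_path, config.reac_path,
        config.hist_path, config.column_map, config.encoding)
    retained, excl_counts = report_model.apply_exclusions(
        cases, config.exclusion_rules)
    if not retained:
        raise ValueError("no cases retained after exclusions")
    smq = meddra_smq.load_smq(config.smq_path)
    flags = meddra_smq.flag_cases(retained, smq, config.scope_filter)

    present = {name for c in retained for name in c.drug_names()}
    class_groups: dict[str, DrugGroup] = {}
    member_groups: list[DrugGroup] = []
    labels: dict[str, str] = {}
    for cls_name, path in config.class_paths.items():
        group = DrugGroup.from_file(path, cls_name)
        class_groups[cls_name] = group
        for drug in sorted(group.members):
            if drug not in present:
                logger.warning("drug %r (class %s) absent from the data; "
                               "no row emitted", drug, cls_name)
                continue
            member_groups.append(DrugGroup.single(drug))
            labels[drug] = cls_name

    per_class = _score_groups(retained, list(class_groups.values()), flags,
                              config.counted_roles, config.priors)
    per_drug_parts = []
    for cls_name, group in class_groups.items():
        per_drug_parts.append(per_class[per_class.group_name == cls_name])
        members = [g for g in member_groups if labels[g.name] == cls_name]
        if members:
            per_drug_parts.append(_score_groups(
                retained, members, flags, config.counted_roles, config.priors,
                labels))
    per_drug = pd.concat(per_drug_parts, ignore_index=True)

    strata_parts = []
    for cls_name, group in class_groups.items():
        s = contingency.stratify_counts(retained, group, flags,
                                        roles=config.counted_roles)
        s.insert(0, "drug_class", cls_name)
        strata_parts.append(s)
    strata = pd.concat(strata_parts, ignore_index=True)

    names = list(class_groups)
    combo_parts = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            combo_parts.append(contingency.find_combination_cases(
                retained, class_groups[a], class_groups[b], flags))
    combinations = (pd.concat(combo_parts, ignore_index=True)
                    if combo_parts else pd.DataFrame())

    log: dict = {
        "n_plus_plus": len(retained),
        "exclusion_counts": dict(excl_counts),
        "smq_term_count": len(smq.terms),
        "scope_filter": config.scope_filter,
    }
    bundle = ResultBundle(per_drug=per_drug, per_class=per_class,
                          strata=strata, combinations=combinations, log=log)
    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def render_scored_table(df: pd.DataFrame, dash_undefined: bool = True) -> pd.DataFrame:
    """Human-readable view: ICs rounded to 2 decimals, "IC (CI)" column.

    With ``dash_undefined`` (the default), rows for groups with no exposed
    cases at all (N1+ = 0) render an em-dash instead of a prior-only IC;
    the underlying numeric value is still present in the unrendered frame.
    """
    out = df[["group_name", "drug_class", "n11", "n1plus"]].copy()
    text = []
    for r in df.itertuples(index=False):
        if dash_undefined and r.n1plus == 0:
            text.append("―")
        else:
            text.append(f"{r.e_ic:.2f} ({r.ic025:.2f} to {r.ic975:.2f})"
                        + (" *" if r.classification == "signal" else "")
                        + (" †" if r.classification == "inverse" else ""))
    out["ic_95ci"] = text
    return out


def _write_bundle(bundle: ResultBundle, config: RunConfig) -> None:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "per_drug.tsv": bundle.per_drug,
        "per_class.tsv": bundle.per_class,
        "strata.tsv": bundle.strata,
        "combinations.tsv": bundle.combinations,
        "per_drug_rendered.tsv": render_scored_table(
            bundle.per_drug, config.dash_undefined),
    }
    checksums = {}
    for name, df in files.items():
        content = df.to_csv(sep="\t", index=False)
        (out / name).write_text(content, encoding="utf-8")
        checksums[name] = hashlib.md5(content.encode("utf-8")).hexdigest()
    bundle.log["checksums"] = checksums
    (out / "run_log.yaml").write_text(
        yaml.safe_dump(bundle.log, sort_keys=True), encoding="utf-8")


__all__ = ["ResultBundle", "RunConfig", "render_scored_table", "run_analysis",
           "score_counts"]
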