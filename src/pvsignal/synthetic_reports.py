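"""Synthetic four-table spontaneous-report databases with known ground truth.

Real pharmacovigilance databases cannot be redistributed, so every pipeline
stage here is exercised against simulated ones.  The generator emulates the
structure of a spontaneous reporting system: each simulated case gets
demographics, a set of drug exposures, and adverse-event preferred terms;
the target condition occurs with a probability shaped by per-drug
reporting-ratio multipliers, so the asymptotic information component of each
drug is known in closed form and parameter recovery can be tested.

Generative model
----------------
* Demographics: sex and decade age band are drawn from configured
  categorical distributions.
* Exposures: each modeled drug is an independent Bernoulli draw with its
  marginal probability; optional pairwise co-prescription multipliers tilt
  the odds of one drug when its partner is present.  A case exposed to no
  modeled drug represents a report about drugs outside the modeled set and
  receives a filler exposure so every report lists a drug.
* Target event: a case exposed to drugs d₁..dₖ develops the target condition
  with probability 1 − Π(1 − p₀·λ_d) (independent-hazard composition, capped
  below 1); an unexposed case with the baseline probability p₀.  λ_d = 1
  therefore means "reports the event at the background rate" and the drug's
  asymptotic IC is ≈ 0; a rare drug with λ_d = 4 has an asymptotic IC near
  log₂ 4 = 2 bits.
* Coding: a case with the condition receives 1–3 preferred terms drawn from
  the configured narrow/broad PT pool (duplicates collapse, exercising
  case-level deduplication); other cases receive one background PT.
* Exclusion noise: disjoint random subsets of cases get a subjective age
  term, a missing sex or a missing age, so the exclusion stage has work to
  do.

Identical config and seed give byte-identical output files.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .report_model import (
    CaseReport,
    DrugExposure,
    DrugRole,
    NUMERIC_AGE_BANDS,
    normalize_drug_name,
    write_report_tables,
)

logger = logging.getLogger("pvsignal")

_ENUM_LIMIT = 15  # exact truth enumeration up to 2^15 exposure patterns


@dataclass(frozen=True)
class DrugSpec:
    """One simulated drug: marginal exposure probability and event behavior.

    ``reporting_ratio`` is the multiplier λ on the baseline event probability
    among the drug's cases; λ = 1 is a null drug, λ > 1 signals, λ < 1
    inverse-signals.
    """

    name: str
    exposure_prob: float
    reporting_ratio: float = 1.0
    drug_class: str | None = None
    role: DrugRole = DrugRole.SUSPECTED

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", normalize_drug_name(self.name))
        if not 0 <= self.exposure_prob <= 1:
            raise ValueError(f"{self.name}: exposure_prob outside [0, 1]")
        if self.reporting_ratio < 0:
            raise ValueError(f"{self.name}: reporting_ratio must be >= 0")


@dataclass
class SyntheticConfig:
    """Full specification of one simulated reporting database."""

    n_cases: int
    drug_specs: list[DrugSpec]
    baseline_event_prob: float = 0.02
    sex_probs: dict[str, float] = field(
        default_factory=lambda: {"female": 0.5, "male": 0.5})
    age_band_probs: dict[str, float] = field(
        default_factory=lambda: {b: p for b, p in zip(
            NUMERIC_AGE_BANDS, (0.10, 0.10, 0.15, 0.25, 0.25, 0.12, 0.03))})
    co_rx: dict[tuple[str, str], float] | None = None
    narrow_pts: dict[str, float] = field(
        default_factory=lambda: {"PT_ANGIO_N1": 2.0, "PT_ANGIO_N2": 1.0})
    broad_pts: dict[str, float] = field(
        default_factory=lambda: {"PT_ANGIO_B1": 1.0})
    background_pts: tuple[str, ...] = ("PT_OTHER_1", "PT_OTHER_2", "PT_OTHER_3")
    exclusion_noise: dict[str, float] = field(default_factory=dict)
    require_exposure: bool = False
    event_prob_cap: float = 0.99
    year_range: tuple[int, int] = (2010, 2019)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not 0 < self.baseline_event_prob < 1:
            raise ValueError("baseline_event_prob must lie in (0, 1)")
        for dist, label in ((self.sex_probs, "sex_probs"),
                            (self.age_band_probs, "age_band_probs")):
            if any(p < 0 for p in dist.values()) or not math.isclose(
                    sum(dist.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"{label} must be non-negative and sum to 1")
        names = [d.name for d in self.drug_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names in drug_specs")
        if self.co_rx:
            seen: set[str] = set()
            for (a, b), mult in self.co_rx.items():
                if mult <= 0:
                    raise ValueError("co_rx multipliers must be positive")
                if a not in names or b not in names:
                    raise ValueError(f"co_rx pair ({a}, {b}) names unknown drugs")
                if a in seen or b in seen or a == b:
                    raise ValueError("each drug may appear in at most one co_rx pair")
                seen.update((a, b))
        bad = set(self.exclusion_noise) - {"subjective_age", "missing_sex",
                                           "missing_age"}
        if bad:
            raise ValueError(f"unknown exclusion_noise keys {sorted(bad)}")
        if sum(self.exclusion_noise.values()) >= 1:
            raise ValueError("exclusion_noise fractions must sum to < 1")

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SyntheticConfig":
        raw = dict(raw)
        raw["drug_specs"] = [
            DrugSpec(**{**d, "role": DrugRole(d.get("role", "suspected"))})
            for d in raw["drug_specs"]
        ]
        if raw.get("co_rx"):
            raw["co_rx"] = {(p["a"], p["b"]): float(p["odds_multiplier"])
                            for p in raw["co_rx"]}
        for key in ("background_pts", "year_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# --------------------------------------------------------------------------
# sampling


def _sample_exposures(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_cases × n_drugs) boolean exposure matrix."""
    n, drugs = cfg.n_cases, cfg.drug_specs
    probs = np.array([d.exposure_prob for d in drugs])
    x = rng.random((n, len(drugs))) < probs
    if cfg.co_rx:
        index = {d.name: j for j, d in enumerate(drugs)}
        for (a, b), mult in cfg.co_rx.items():
            ja, jb = index[a], index[b]
            qb = probs[jb]
            odds = mult * qb / (1 - qb) if qb < 1 else np.inf
            p_cond = odds / (1 + odds)
            mask = x[:, ja]
            x[mask, jb] = rng.random(int(mask.sum())) < p_cond
    if cfg.require_exposure:
        for _ in range(10_000):
            empty = ~x.any(axis=1)
            if not empty.any():
                break
            x[empty] = rng.random((int(empty.sum()), len(drugs))) < probs
        else:
            raise RuntimeError("could not satisfy require_exposure")
    return x


def _event_probs(cfg: SyntheticConfig, x: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-case target-event probability and number of capped cases."""
    p0 = cfg.baseline_event_prob
    miss = np.array([1.0 - p0 * d.reporting_ratio for d in cfg.drug_specs])
    capped_channel = miss <= 0
    miss = np.clip(miss, 1e-12, 1.0)
    p = 1.0 - np.exp(x @ np.log(miss))
    p[~x.any(axis=1)] = p0
    n_capped = int((p > cfg.event_prob_cap).sum() + x[:, capped_channel].any(axis=1).sum())
    return np.minimum(p, cfg.event_prob_cap), n_capped


def generate(config: SyntheticConfig) -> list[CaseReport]:
    """Simulate one reporting database as a list of case reports.

    Deterministic in ``config.seed``; see the module docstring for the
    generative model.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drugs = config.drug_specs

    sexes = list(config.sex_probs)
    sex_draw = rng.choice(len(sexes), size=n, p=list(config.sex_probs.values()))
    bands = list(config.age_band_probs)
    band_draw = rng.choice(len(bands), size=n,
                           p=list(config.age_band_probs.values()))
    years = rng.integers(config.year_range[0], config.year_range[1] + 1, size=n)

    x = _sample_exposures(config, rng)
    p_event, n_capped = _event_probs(config, x)
    if n_capped:
        logger.warning("event probability cap hit for %d cases", n_capped)
    flagged = rng.random(n) < p_event

    target_pts = list(config.narrow_pts) + list(config.broad_pts)
    weights = np.array(list(config.narrow_pts.values())
                       + list(config.broad_pts.values()), dtype=float)
    weights /= weights.sum()
    n_pts = rng.integers(1, 4, size=n)  # 1..3 draws, duplicates collapse
    pt_draws = rng.choice(len(target_pts), size=(n, 3), p=weights)
    bg_draws = rng.choice(len(config.background_pts), size=n)

    # disjoint corruption subsets for exclusion noise
    order = rng.permutation(n)
    noise_band = np.full(n, False)
    noise_sex = np.full(n, False)
    noise_age = np.full(n, False)
    start = 0
    for key, mask in (("subjective_age", noise_band),
                      ("missing_sex", noise_sex),
                      ("missing_age", noise_age)):
        k = int(round(config.exclusion_noise.get(key, 0.0) * n))
        mask[order[start:start + k]] = True
        start += k

    cases: list[CaseReport] = []
    width = max(7, len(str(n)))
    for i in range(n):
        age_band = bands[band_draw[i]]
        sex = sexes[sex_draw[i]]
        if noise_band[i]:
            age_band = "subjective"
        elif noise_age[i]:
            age_band = "missing"
        if noise_sex[i]:
            sex = "missing"
        exposures = [DrugExposure(drug_name=drugs[j].name, role=drugs[j].role)
                     for j in np.flatnonzero(x[i])]
        if not exposures:
            exposures = [DrugExposure(drug_name="background-drug",
                                      role=DrugRole.SUSPECTED)]
        if flagged[i]:
            events = {target_pts[j] for j in pt_draws[i, :n_pts[i]]}
        else:
            events = {config.background_pts[bg_draws[i]]}
        cases.append(CaseReport(
            case_id=f"SIM-{i:0{width}d}",
            sex=sex,
            age_band=age_band,
            drugs=exposures,
            events=events,
            report_year=int(years[i]),
        ))
    return cases


def generate_database(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the four-table layout plus a truth manifest."""
    cases = generate(config)
    paths = write_report_tables(cases, out_dir)
    truth = truth_table(config)
    manifest = {
        "seed": config.seed,
        "n_cases": config.n_cases,
        "truth": truth.to_dict(orient="records"),
    }
    manifest_path = Path(out_dir) / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    paths["manifest"] = manifest_path
    return paths


# --------------------------------------------------------------------------
# ground truth


def _exposure_distribution(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exact joint exposure distribution by enumeration (≤ 2^15 patterns).

    Returns (patterns, probabilities); patterns is a boolean matrix with one
    row per exposure subset.
    """
    drugs = cfg.drug_specs
    k = len(drugs)
    if k > _ENUM_LIMIT:
        raise ValueError(
            f"exact enumeration supports at most {_ENUM_LIMIT} drugs (got {k})")
    probs = np.array([d.exposure_prob for d in drugs])
    patterns = np.array(list(itertools.product((False, True), repeat=k)))
    p = np.where(patterns, probs, 1 - probs).prod(axis=1)
    if cfg.co_rx:
        index = {d.name: j for j, d in enumerate(drugs)}
        for (a, b), mult in cfg.co_rx.items():
            ja, jb = index[a], index[b]
            qb = probs[jb]
            odds = mult * qb / (1 - qb)
            p_cond = odds / (1 + odds)
            # replace the independent factor for b where a is present
            adj = np.where(patterns[:, jb], p_cond, 1 - p_cond)
            base = np.where(patterns[:, jb], qb, 1 - qb)
            mask = patterns[:, ja]
            p[mask] = p[mask] / base[mask] * adj[mask]
    if cfg.require_exposure:
        none = ~patterns.any(axis=1)
        p[none] = 0.0
        p /= p.sum()
    return patterns, p


def truth_table(config: SyntheticConfig) -> pd.DataFrame:
    """Closed-form expected counts and asymptotic IC per modeled drug.

    Columns: ``drug, expected_n11, expected_n1plus, expected_nplus1,
    expected_nplusplus, asymptotic_ic`` where the asymptotic IC is
    log₂ P(event | exposed) / P(event) under the generative model, the value
    the pipeline's estimate converges to as the database grows.  Expected
    counts refer to the cases retained after exclusions.
    """
    drugs = config.drug_specs
    p0 = config.baseline_event_prob
    lam = np.array([d.reporting_ratio for d in drugs])
    retention = 1.0 - sum(config.exclusion_noise.values())
    n_ret = config.n_cases * retention

    if len(drugs) <= _ENUM_LIMIT:
        patterns, pat_p = _exposure_distribution(config)
        ev = 1.0 - np.where(patterns, 1 - p0 * lam, 1.0).prod(axis=1)
        ev[~patterns.any(axis=1)] = p0
        ev = np.minimum(ev, config.event_prob_cap)
        p_event = float(pat_p @ ev)
        q_marg = pat_p @ patterns  # per-drug marginal exposure probability
        p_joint = (pat_p * ev) @ patterns  # P(exposed to d AND event)
    else:
        if config.co_rx or config.require_exposure:
            raise ValueError(
                "closed-form truth beyond the enumeration limit requires "
                "independent exposures (no co_rx, require_exposure=False)")
        q = np.array([d.exposure_prob for d in drugs])
        q_marg = q
        p_none = float(np.prod(1 - q))
        p_event_exposed_any = 1.0 - float(np.prod(1 - q * p0 * lam))
        p_event = p_none * p0 + p_event_exposed_any
        # P(event | exposed to d): condition on X_d = 1, others independent
        others = np.array([
            np.prod(np.delete(1 - q * p0 * lam, j)) for j in range(len(q))])
        p_ev_given = 1.0 - (1 - p0 * lam) * others
        p_joint = q * p_ev_given

    rows = []
    for j, d in enumerate(drugs):
        p_ev_given_d = p_joint[j] / q_marg[j] if q_marg[j] > 0 else float("nan")
        ic = (math.log2(p_ev_given_d / p_event)
              if q_marg[j] > 0 and p_ev_given_d > 0 else float("nan"))
        rows.append({
            "drug": d.name,
            "expected_n11": n_ret * p_joint[j],
            "expected_n1plus": n_ret * q_marg[j],
            "expected_nplus1": n_ret * p_event,
            "expected_nplusplus": n_ret,
            "asymptotic_ic": ic,
        })
    return pd.DataFrame(rows)


__all__ = ["DrugSpec", "SyntheticConfig", "generate", "generate_database",
           "truth_table"]
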