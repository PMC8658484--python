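"""Bundled reference counts from a published JADER angioedema screen.

A published spontaneous-report screen of ACE-inhibitor and DPP-4-inhibitor
angioedema reports prints, for each drug and for each class, the case counts
N11 and N1+ together with the IC and its 95% credible interval, the grand
total N++ = 534,287 retained cases, and the per-stratum demographic counts.
The one quantity it does not print is the event margin N+1 (the total number
of angioedema cases), which :func:`pvsignal.bcpnn.calibrate_margin` recovers
from the printed ICs.  These tables are the golden inputs for end-to-end
verification of the scoring pipeline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Retained patient reports (N++) in the reference screen.
REFERENCE_TOTAL_CASES = 534_287


def _fixture_path(name: str):
    return resources.files("pvsignal") / "fixtures" / name


def fixture_path(name: str) -> str:
    """Filesystem path of a bundled fixture file."""
    return str(_fixture_path(name))


def load_reference_counts(drug_class: str) -> pd.DataFrame:
    """Published per-drug counts and IC values for ``"ace"`` or ``"dpp4"``.

    Columns: ``group_name, n11, n1plus, ic, ic025, ic975, classification``;
    the class-total row comes first.  Rows whose IC the source left blank
    (zero-count drugs rendered as a dash) carry NaN.
    """
    if drug_class not in ("ace", "dpp4"):
        raise ValueError("drug_class must be 'ace' or 'dpp4'")
    with _fixture_path(f"reference_counts_{drug_class}.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_strata() -> pd.DataFrame:
    """Published per-stratum N11/N1+ and reporting rates for both classes."""
    with _fixture_path("reference_strata.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def calibration_rows() -> list[tuple[int, int, float]]:
    """(N11, N1+, published IC) rows for margin calibration.

    Uses the ACE-inhibitor table (13 rows: the class total plus 12 drugs),
    whose printed ICs jointly pin down the unprinted event margin.
    """
    df = load_reference_counts("ace")
    return [(int(r.n11), int(r.n1plus), float(r.ic))
            for r in df.itertuples(index=False)]


__all__ = ["REFERENCE_TOTAL_CASES", "calibration_rows", "fixture_path",
           "load_reference_counts", "load_reference_strata"]
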