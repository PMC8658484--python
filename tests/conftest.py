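from __future__ import annotations

import pytest

from pvsignal import reference
from pvsignal.meddra_smq import SMQDefinition, load_smq
from pvsignal.report_model import CaseReport, DrugExposure, DrugRole


@pytest.fixture(scope="session")
def toy_smq() -> SMQDefinition:
    """Bundled toy angioedema SMQ: two narrow PTs and one broad PT."""
    return load_smq(reference.fixture_path("smq_angioedema_toy.tsv"))


def make_case(case_id, drugs=(), events=(), sex="female", age_band="60-69",
              role=DrugRole.SUSPECTED, year=2015):
    """Terse CaseReport builder for tests."""
    return CaseReport(
        case_id=case_id,
        sex=sex,
        age_band=age_band,
        drugs=[DrugExposure(drug_name=d, role=role) if isinstance(d, str) else d
               for d in drugs],
        events=set(events),
        report_year=year,
    )


@pytest.fixture
def small_cases() -> list[CaseReport]:
    """Six cases with known exposures/events for counting tests."""
    return [
        make_case("c1", ["enalapril"], ["PT_ANGIO_N1"], sex="female"),
        make_case("c2", ["enalapril", "imidapril"], ["PT_ANGIO_B1"], sex="male"),
        make_case("c3", ["imidapril"], ["PT_OTHER_1"], sex="female",
                  age_band="40-49"),
        make_case("c4", ["vildagliptin", "enalapril"], ["PT_ANGIO_N2"],
                  sex="male", age_band="70-79"),
        make_case("c5", ["metformin"], ["PT_OTHER_2"], sex="male"),
        make_case("c6", [], ["PT_ANGIO_N1"], sex="female", age_band="<40"),
    ]
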