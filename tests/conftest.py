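import logging

import pytest

from credmeta.study_table import GenotypeCounts, StudyRecord

logging.getLogger("credmeta").setLevel(logging.ERROR)

CSV_HEADER = (
    "study_id,first_author,pub_year,disease,variant_id,gene,ethnicity,"
    "case_hom_major,case_het,case_hom_minor,ctrl_hom_major,ctrl_het,ctrl_hom_minor"
)


@pytest.fixture
def write_csv(tmp_path):
    """Factory writing raw CSV rows (strings) under the standard header."""

    def _write(*rows: str, header: str = CSV_HEADER):
        path = tmp_path / "studies.csv"
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _write


def make_record(
    study_id: str = "S01",
    pub_year: int = 2010,
    cases: tuple = (70, 20, 10),
    controls: tuple = (80, 15, 5),
    variant_id: str = "rs1",
    disease: str = "LC",
    ethnicity: str = "Asian",
    is_first_published: bool = False,
) -> StudyRecord:
    return StudyRecord(
        study_id=study_id,
        first_author=f"A-{study_id}",
        pub_year=pub_year,
        disease=disease,
        variant_id=variant_id,
        gene="CHRNA3",
        ethnicity=ethnicity,
        cases=GenotypeCounts(*cases),
        controls=GenotypeCounts(*controls),
        is_first_published=is_first_published,
    )
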