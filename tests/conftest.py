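import numpy as np
import pytest

from lfqenrich import (
    AnalysisConfig,
    Fraction,
    IntensityTable,
    Prep,
    ProteinRecord,
    SampleDescriptor,
)


def make_design(n_per_condition: int = 2, preps=(Prep.GEL,)) -> list[SampleDescriptor]:
    design = []
    for prep in preps:
        for fraction in Fraction:
            for r in range(1, n_per_condition + 1):
                design.append(
                    SampleDescriptor(
                        f"{prep.value}_{fraction.value}_{r}", fraction, prep, r
                    )
                )
    return design


def make_table(values, mask=None, design=None, scale="raw", records=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    if design is None:
        # one condition per column pair: MBR+ then MBR- with gel prep
        assert values.shape[1] % 2 == 0
        half = values.shape[1] // 2
        design = [
            SampleDescriptor(f"plus_{r}", Fraction.MBR_PLUS, Prep.GEL, r)
            for r in range(1, half + 1)
        ] + [
            SampleDescriptor(f"minus_{r}", Fraction.MBR_MINUS, Prep.GEL, r)
            for r in range(1, half + 1)
        ]
    if records is None:
        records = [ProteinRecord(f"P{i + 1}") for i in range(values.shape[0])]
    return IntensityTable(
        records=records, design=design, values=values, mask=np.asarray(mask, bool),
        scale=scale,
    )


@pytest.fixture
def config():
    return AnalysisConfig(seed=0)


@pytest.fixture
def protein_groups_file(tmp_path):
    """Three proteins, four samples (2 MBR+, 2 MBR- gel), one zero cell and
    one reverse-flagged row."""
    header = [
        "Majority protein IDs", "Gene names", "Reverse", "Potential contaminant",
        "Only identified by site", "Peptide counts (unique)",
        "LFQ intensity plus_1", "LFQ intensity plus_2",
        "LFQ intensity minus_1", "LFQ intensity minus_2",
    ]
    rows = [
        ["P1", "GENE1", "", "", "", "3", "100", "120", "90", "95"],
        ["P2", "GENE2", "+", "", "", "2;1", "50", "0", "60", "70"],
        ["P3", "", "", "", "", "1", "10", "11", "12", "13"],
    ]
    path = tmp_path / "proteinGroups.tsv"
    path.write_text(
        "\n".join("\t".join(r) for r in [header, *rows]) + "\n"
    )
    design_path = tmp_path / "design.tsv"
    design_rows = [
        ["sample_id", "fraction", "prep", "replicate"],
        ["plus_1", "MBR_plus", "gel", "1"],
        ["plus_2", "MBR_plus", "gel", "2"],
        ["minus_1", "MBR_minus", "gel", "1"],
        ["minus_2", "MBR_minus", "gel", "2"],
    ]
    design_path.write_text(
        "\n".join("\t".join(r) for r in design_rows) + "\n"
    )
    return path, design_path
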