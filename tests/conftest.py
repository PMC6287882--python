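import pandas as pd
import pytest

from funcat import (
    AnnotationTable,
    CategoryPath,
    DifferentialTable,
    SimulationConfig,
    simulate_annotation,
)


@pytest.fixture
def small_annotation() -> AnnotationTable:
    """Ten genes over a tiny 3-level hierarchy; hand-checkable counts."""
    entries = {
        "g01": CategoryPath.parse("Proteolysis Proteasome: E3: F-box"),
        "g02": CategoryPath.parse("Proteolysis Proteasome: E3: F-box"),
        "g03": CategoryPath.parse("Proteolysis Proteasome: E3: SKR"),
        "g04": CategoryPath.parse("Proteolysis Proteasome: 19S subunit"),
        "g05": CategoryPath.parse("Metabolism: lipid"),
        "g06": CategoryPath.parse("Metabolism: lipid: beta oxidation"),
        "g07": CategoryPath.parse("Metabolism"),
        "g08": CategoryPath.parse("Stress response: pathogen"),
        "g09": CategoryPath.parse("Stress response: heavy metal"),
        "g10": CategoryPath.parse("Transcription factor"),
    }
    return AnnotationTable(entries)


@pytest.fixture
def toy_de() -> DifferentialTable:
    """Six genes spanning the fold/FDR selection boundaries."""
    return DifferentialTable.from_records(
        [
            ("g01", 1.5, 0.005),   # in up-set
            ("g02", 1.0, 0.001),   # exactly 2-fold: excluded (strict)
            ("g03", 2.5, 0.010),   # FDR exactly at cut: excluded (strict)
            ("g04", -2.0, 0.0001), # in down-set
            ("g05", 0.2, 0.5),     # null
            ("g06", 3.0, 0.002),   # in up-set, and in 4-fold set (log2fc > 2)
        ],
        label="toy",
    )


@pytest.fixture(scope="session")
def sim_annotation_1k() -> AnnotationTable:
    """A 1,000-gene synthetic universe shared across tests."""
    return simulate_annotation(
        SimulationConfig(seed=42, n_genes=1000, n_level1=10, query_size=None,
                         regulated_fraction=0.05)
    )
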