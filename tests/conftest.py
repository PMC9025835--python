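import pandas as pd
import pytest

from mirank import SimulationManifest, default_dialects


@pytest.fixture
def dialects():
    return default_dialects()


@pytest.fixture
def small_manifest():
    """A compact universe with planted regulators and alias groups."""
    return SimulationManifest(
        seed=42,
        n_mirnas=30,
        n_planted=4,
        alias_groups=(
            ("hsa-miR-901a-3p", "hsa-miR-901b-3p", "hsa-miR-901c-3p"),
            ("hsa-miR-902-1-5p", "hsa-miR-902-2-5p"),
        ),
    )


@pytest.fixture
def record_frame():
    """A tiny standardized record table covering two miRNAs."""
    return pd.DataFrame({
        "mirna_key": ["mir-a", "mir-a", "mir-a", "mir-b"],
        "gene_symbol": ["BDNF", "BDNF", "HTR1A", "NR3C1"],
        "evaluation": [1.0, 1.4, 0.9, 1.5],
        "database_name": ["mirwalk", "mirdb", "mirmap", "mirmap"],
    })
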