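from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

REPO_ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def somatic_example_path() -> Path:
    """Worked-example table: the 11 published WT/GCF testis average read
    counts for the gonad-specific genes expressed in somatic cells."""
    return REPO_ROOT / "examples" / "testis_somatic_counts.tsv"


@pytest.fixture(scope="session")
def somatic_example(somatic_example_path) -> pd.DataFrame:
    return pd.read_csv(somatic_example_path, sep="\t", index_col=0)


@pytest.fixture()
def write_tsv(tmp_path):
    """Write a TSV from text, returning its path."""

    def _write(name: str, text: str) -> Path:
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
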