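import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def small_table() -> pd.DataFrame:
    """Three well-formed peptide rows, one protein with two peptides."""
    return pd.DataFrame(
        {
            "experiment_id": ["exp1"] * 3,
            "protein_accession": ["P1", "P1", "P2"],
            "peptide_sequence": ["PEPTIDEK", "AELVQK", "GLSDGEWQLVLNVWGK"],
            "confidence_pct": [99.0, 96.5, 97.2],
            "area_114": [1000.0, 800.0, 1200.0],
            "area_115": [1100.0, 700.0, 1150.0],
            "area_116": [950.0, 820.0, 1300.0],
            "area_117": [1020.0, 760.0, 1250.0],
        }
    )


def make_scored_observations(
    ln_ratios, p_values, significant, directions, accession="P1", contrast="c"
) -> pd.DataFrame:
    """Assemble a scored peptide-observation frame for rollup tests."""
    n = len(ln_ratios)
    return pd.DataFrame(
        {
            "experiment_id": ["exp1"] * n,
            "protein_accession": [accession] * n,
            "peptide_sequence": [f"PEP{i}K" for i in range(n)],
            "contrast": [contrast] * n,
            "ln_ratio": np.asarray(ln_ratios, float),
            "p_value": np.asarray(p_values, float),
            "significant": np.asarray(significant, bool),
            "direction": list(directions),
        }
    )
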