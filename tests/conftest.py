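import numpy as np
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


@pytest.fixture
def replicate_df():
    """Minimal well-formed replicate table: one level, two runs, duplicates."""

    def make(values, nominal=1.5, analyzer="cobas", level_id="S1"):
        values = np.asarray(values, dtype=float)
        n_runs = max(1, len(values) // 2)
        rows = []
        for i, v in enumerate(values):
            rows.append(
                {
                    "analyzer": analyzer,
                    "matrix": "urine",
                    "level_id": level_id,
                    "nominal_conc": nominal,
                    "run_id": f"day{i // 2 + 1:02d}",
                    "replicate_index": i % 2 + 1,
                    "value": v,
                    "raw_response": np.nan,
                }
            )
        return pd.DataFrame(rows)

    return make


@pytest.fixture
def paired_df():
    """Paired-totals frame builder from two arrays of totals (mg)."""

    def make(a, b):
        return pd.DataFrame(
            {
                "patient_id": [str(i + 1) for i in range(len(a))],
                "method_a_total": np.asarray(a, dtype=float),
                "method_b_total": np.asarray(b, dtype=float),
            }
        )

    return make
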