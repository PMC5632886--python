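"""Small shared helpers for the test suite."""

import numpy as np
import pandas as pd

from xyloval.study_data import PairedComparisonTable


def make_pairs(a, b) -> PairedComparisonTable:
    return PairedComparisonTable(
        pd.DataFrame(
            {
                "patient_id": [str(i + 1) for i in range(len(a))],
                "method_a_total": np.asarray(a, dtype=float),
                "method_b_total": np.asarray(b, dtype=float),
            }
        )
    )
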