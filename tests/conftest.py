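import numpy as np
import pandas as pd
import pytest

from acidep import ExpressionMatrix


def make_matrix(values: dict[str, list[float]], conditions: list[str],
                n_replicates: int, scale: str = "linear") -> ExpressionMatrix:
    """Build a matrix from per-feature value lists laid out as
    condition-major replicate blocks."""
    sample_ids, meta_rows = [], []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            sid = f"{cond}_r{rep}"
            sample_ids.append(sid)
            meta_rows.append({"sample_id": sid, "condition": cond, "replicate": rep})
    frame = pd.DataFrame(values, index=sample_ids).T
    frame.index.name = "feature_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return ExpressionMatrix(values=frame, sample_meta=meta, scale=scale)


@pytest.fixture
def three_condition_matrix() -> ExpressionMatrix:
    """3 features x (3 conditions x 4 replicates), linear scale."""
    rng = np.random.default_rng(42)
    values = {
        f"g{i}": list(rng.uniform(50, 200, 12).round(3)) for i in range(1, 4)
    }
    return make_matrix(values, ["pH7.4", "pH6.8", "pH5.9"], 4)
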