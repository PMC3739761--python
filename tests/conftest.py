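import numpy as np
import pandas as pd
import pytest

from sciseq.containers import ExpressionStudy


def make_study(
    values: dict[str, list[float]],
    stages: dict[str, str],
    ci_lo: dict[str, list[float]] | None = None,
    ci_hi: dict[str, list[float]] | None = None,
    features: list[str] | None = None,
    **kwargs,
) -> ExpressionStudy:
    """Small-study builder: values maps sample id -> per-feature FPKMs."""
    n = len(next(iter(values.values())))
    features = features or [f"g{i+1}" for i in range(n)]
    idx = pd.Index(features, name="feature")
    samples = pd.DataFrame(
        {
            "stage": [stages[s] for s in values],
            "replicate": list(range(1, len(values) + 1)),
        },
        index=pd.Index(list(values), name="sample_id"),
    )
    return ExpressionStudy(
        values=pd.DataFrame(values, index=idx),
        samples=samples,
        ci_lo=None if ci_lo is None else pd.DataFrame(ci_lo, index=idx),
        ci_hi=None if ci_hi is None else pd.DataFrame(ci_hi, index=idx),
        **kwargs,
    )


@pytest.fixture
def two_stage_study() -> ExpressionStudy:
    """3 genes, 2 stages × 3 replicates, no CIs."""
    return make_study(
        values={
            "c1": [1.0, 10.0, 0.4],
            "c2": [2.0, 11.0, 0.4],
            "c3": [3.0, 12.0, 0.4],
            "t1": [2.0, 1.0, 0.1],
            "t2": [3.0, 1.2, 0.1],
            "t3": [4.0, 1.4, 0.1],
        },
        stages={"c1": "CTR", "c2": "CTR", "c3": "CTR",
                "t1": "D2", "t2": "D2", "t3": "D2"},
    )
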