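import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from exprvar.io import CtTable, ExpressionMatrix, SampleGroups

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        {
            "c1": [10.0, 1.0, 5.0],
            "c2": [10.0, 3.0, 6.0],
            "s1": [10.0, 2.0, 7.0],
            "s2": [10.0, 4.0, 8.0],
        },
        index=pd.Index(["gA", "gB", "gC"], name="feature_id"),
    )
    return ExpressionMatrix(data, "linear")


@pytest.fixture
def tiny_groups() -> SampleGroups:
    return SampleGroups(
        assignment={"c1": "control", "c2": "control", "s1": "case", "s2": "case"}
    )


def make_ct_table(values: dict) -> CtTable:
    """Build a CtTable from {(subject, timepoint, gene): ct}."""
    rows = [
        {"subject_id": s, "timepoint": t, "gene": g, "ct": ct}
        for (s, t, g), ct in values.items()
    ]
    return CtTable(pd.DataFrame(rows))


@pytest.fixture
def paired_ct() -> CtTable:
    """Two subjects, two timepoints, reference gene + two targets.

    Baseline dCt: geneX = 2 for both subjects, geneY = 3 and 5.
    Follow-up dCt: geneX = 1 (one cycle less => ddCt = -1, rq = 2),
    geneY unchanged per subject.
    """
    values = {}
    for subj, ref_ct in (("S1", 20.0), ("S2", 21.0)):
        values[(subj, "0W", "REF")] = ref_ct
        values[(subj, "12W", "REF")] = ref_ct + 0.5
        values[(subj, "0W", "geneX")] = ref_ct + 2.0
        values[(subj, "12W", "geneX")] = ref_ct + 0.5 + 1.0
    values[("S1", "0W", "geneY")] = 20.0 + 3.0
    values[("S2", "0W", "geneY")] = 21.0 + 5.0
    values[("S1", "12W", "geneY")] = 20.5 + 3.0
    values[("S2", "12W", "geneY")] = 21.5 + 5.0
    return make_ct_table(values)
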