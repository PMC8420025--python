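import numpy as np
import pandas as pd
import pytest

from tpakit.io_tables import IntensityMatrix, SampleAnnotation
from tpakit.preprocess import LogMatrix


def make_annotation(groups: dict[str, int], n_tech: int = 2) -> SampleAnnotation:
    """Annotation with run ids '<group><s>.<r>'."""
    rows = []
    for group, n in groups.items():
        for s in range(1, n + 1):
            for r in range(1, n_tech + 1):
                rows.append((f"{group}{s}.{r}", f"{group}{s}", group, r))
    df = pd.DataFrame(
        rows, columns=["run_id", "biological_sample_id", "group", "technical_replicate"]
    ).set_index("run_id")
    return SampleAnnotation(df)


def make_log_matrix(values: np.ndarray, run_ids=None, protein_ids=None) -> LogMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    protein_ids = protein_ids or [f"P{i:03d}" for i in range(n)]
    run_ids = run_ids or [f"run{j}" for j in range(m)]
    return LogMatrix(values=pd.DataFrame(values, index=protein_ids, columns=run_ids))


def make_intensity_matrix(raw: np.ndarray, lfq=None, run_ids=None, protein_ids=None) -> IntensityMatrix:
    raw = np.asarray(raw, dtype=float)
    lfq = raw.copy() if lfq is None else np.asarray(lfq, dtype=float)
    n, m = raw.shape
    protein_ids = protein_ids or [f"P{i:03d}" for i in range(n)]
    run_ids = run_ids or [f"run{j}" for j in range(m)]
    flags = pd.DataFrame(
        False, index=protein_ids, columns=["reverse", "site_only", "contaminant"]
    )
    return IntensityMatrix(
        raw=pd.DataFrame(raw, index=protein_ids, columns=run_ids),
        lfq=pd.DataFrame(lfq, index=protein_ids, columns=run_ids),
        flags=flags,
        gene_names=pd.Series([f"G{i}" for i in range(n)], index=protein_ids),
    )


@pytest.fixture
def two_group_annotation() -> SampleAnnotation:
    return make_annotation({"A": 3, "B": 3}, n_tech=2)
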