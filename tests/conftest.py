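import numpy as np
import pandas as pd
import pytest

from driverlens.formats_io import ExpressionMatrix, ProcessKnowledge


def make_expression(values: np.ndarray, conditions: list[str], counts: bool = True,
                    gene_prefix: str = "g", sample_prefix: str = "s") -> ExpressionMatrix:
    genes = [f"{gene_prefix}{i:03d}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j:03d}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(df, dict(zip(samples, conditions)), counts=counts)


@pytest.fixture
def tiny_knowledge() -> ProcessKnowledge:
    """Four genes annotated to two processes, one promoting, one reducing."""
    entries = pd.DataFrame(
        [
            ("g000", "growth", "Increased", 10),
            ("g001", "growth", "Decreased", 5),
            ("g002", "growth", "Affected", 2),
            ("g003", "growth", "Increased", 7),
            ("g000", "death", "Decreased", 3),
            ("g001", "death", "Increased", 4),
            ("g002", "death", "Increased", 1),
            ("g003", "death", "Affected", 6),
        ],
        columns=["gene", "process", "direction", "publication_count"],
    )
    return ProcessKnowledge(entries, {"growth": "promotes_cancer", "death": "reduces_cancer"})


@pytest.fixture
def deg_frame() -> pd.DataFrame:
    genes = [f"g{i:03d}" for i in range(6)]
    return pd.DataFrame(
        {
            "logFC": [2.0, -1.5, 0.5, 3.0, -2.2, 0.0],
            "p_raw": [1e-5, 1e-4, 0.2, 1e-6, 1e-3, 0.9],
            "fdr": [1e-4, 1e-3, 0.3, 1e-5, 5e-3, 0.9],
            "is_deg": [True, True, False, True, True, False],
        },
        index=pd.Index(genes, name="gene"),
    )
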