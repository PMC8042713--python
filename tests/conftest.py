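import numpy as np
import pandas as pd
import pytest

from deconvbench import ExpressionMatrix, generate_source_profiles


def expr(values, unit="count", gene_ids=None, sample_ids=None, lengths=None):
    """Build an ExpressionMatrix from a plain array."""
    v = np.asarray(values, dtype=float)
    gi = gene_ids or [f"g{i}" for i in range(v.shape[0])]
    si = sample_ids or [f"s{j}" for j in range(v.shape[1])]
    gl = None if lengths is None else pd.Series(lengths, index=gi)
    return ExpressionMatrix(pd.DataFrame(v, index=gi, columns=si), unit=unit, gene_lengths=gl)


@pytest.fixture(scope="session")
def small_source():
    """Three-type synthetic source with embedded markers, reused across tests."""
    return generate_source_profiles(
        1000, ["T", "B", "monocytes"], marker_frac=0.02, marker_fold=50.0,
        n_replicates=5, seed=11,
    )
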