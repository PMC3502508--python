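import numpy as np
import pandas as pd
import pytest

import bhlhkit as bk


@pytest.fixture(scope="session")
def preset():
    return bk.default_spec(0)


@pytest.fixture(scope="session")
def small_alignment(preset):
    """Gap-free synthetic alignment, 60 sequences per kingdom."""
    config = bk.GeneratorConfig(n_per_kingdom=60, seed=101, gap_rate=0.0)
    alignment, labels = bk.sample_alignment(preset, config)
    return alignment, labels


@pytest.fixture(scope="session")
def medium_alignment(preset):
    """Gap-free synthetic alignment, 300 sequences per kingdom."""
    config = bk.GeneratorConfig(n_per_kingdom=300, seed=202, gap_rate=0.0)
    alignment, labels = bk.sample_alignment(preset, config)
    return alignment, labels


def constant_alignment(residue: str, n: int = 4, ids=None):
    """All-sites-identical alignment of one residue."""
    sites = bk.DEFAULT_COORDINATES.fixed_sites
    ids = ids or [f"r{i}" for i in range(n)]
    return bk.EnumeratedAlignment.from_records(
        {rid: {s: residue for s in sites} for rid in ids}
    )


def alignment_from_columns(columns: dict[int, list[str]], kingdom=None):
    """Alignment whose listed sites take the given residue columns; all
    other fixed sites are filled with A."""
    n = len(next(iter(columns.values())))
    sites = bk.DEFAULT_COORDINATES.fixed_sites
    recs = {}
    for i in range(n):
        recs[f"r{i}"] = {
            s: (columns[s][i] if s in columns else "A") for s in sites
        }
    k = {f"r{i}": kingdom[i] for i in range(n)} if kingdom is not None else None
    return bk.EnumeratedAlignment.from_records(recs, kingdom=k)


@pytest.fixture(scope="session")
def gaussian_3group():
    """Three well-separated Gaussian groups in 5 dimensions."""
    rng = np.random.default_rng(42)
    n = 120
    means = np.array(
        [
            [0.0, 0, 0, 0, 0],
            [3.0, 1, 0, 0, 0],
            [-2.0, 2, 1, 0, 0],
        ]
    )
    X = np.vstack([rng.normal(m, 1.0, size=(n, 5)) for m in means])
    y = np.repeat(["Animal", "Fungal", "Plant"], n)
    return pd.DataFrame(X), pd.Series(y, index=pd.RangeIndex(3 * n))
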