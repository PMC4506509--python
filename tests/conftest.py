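import numpy as np
import pandas as pd
import pytest

from poldiff.io import RAW, RunDesign, SpectralCountTable


def make_table(rows, kind=RAW):
    """rows: iterable of (protein_id, run_id, count)."""
    return SpectralCountTable(
        data=pd.DataFrame(rows, columns=["protein_id", "run_id", "count"]),
        kind=kind,
    )


def make_design(rows):
    """rows: iterable of (run_id, condition, replicate_index, pair_id)."""
    return RunDesign(
        data=pd.DataFrame(
            rows, columns=["run_id", "condition", "replicate_index", "pair_id"]
        )
    )


@pytest.fixture
def reference_design():
    """3 WT + 3 MUT:N32I (paired 1:1) + 3 EV runs."""
    rows = []
    for k in (1, 2, 3):
        rows.append((f"WT_{k}", "WT", k, f"p{k}"))
    for k in (1, 2, 3):
        rows.append((f"N32I_{k}", "MUT:N32I", k, f"p{k}"))
    for k in (1, 2, 3):
        rows.append((f"EV_{k}", "EV", k, ""))
    return make_design(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
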