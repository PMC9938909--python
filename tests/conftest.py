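import numpy as np
import pandas as pd
import pytest

from phosrewire.core_io import IntensityTable


def make_design(groups: dict[str, tuple[int, int]],
                treatments=("BAS", "INS")) -> pd.DataFrame:
    rows = []
    for g, counts in groups.items():
        for t, n in zip(treatments, counts):
            for r in range(1, n + 1):
                rows.append((f"{g}_{t}_{r}", g, t, r))
    return pd.DataFrame(rows, columns=["sample_id", "group", "treatment",
                                       "replicate"]).set_index("sample_id")


def make_table(values: np.ndarray, groups: dict[str, tuple[int, int]],
               treatments=("BAS", "INS"), scale_state="log2_norm",
               windows=None, accessions=None, sites=None) -> IntensityTable:
    """Small intensity table with auto-generated annotations."""
    design = make_design(groups, treatments)
    n = len(values)
    fids = [f"f{i}" for i in range(n)]
    annotations = pd.DataFrame(
        {
            "protein_accession": accessions or [f"P{i}" for i in range(n)],
            "gene": [f"G{i}" for i in range(n)],
            "site_positions": sites or ["S100"] * n,
            "multiplicity": 1,
            "sequence_window": windows or ["AAAAAAASAAAAAAA"] * n,
        },
        index=pd.Index(fids, name="feature_id"),
    )
    vals = pd.DataFrame(np.asarray(values, float), index=annotations.index,
                        columns=design.index)
    return IntensityTable(values=vals, annotations=annotations,
                          design=design, scale_state=scale_state)


@pytest.fixture
def two_group_table():
    """3 features x (2+2 | 2+2) samples, log2 scale, no missing values."""
    rng = np.random.default_rng(7)
    vals = 20 + rng.normal(0, 0.3, size=(3, 8))
    return make_table(vals, {"CTRL": (2, 2), "DEX": (2, 2)})
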