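import numpy as np
import pandas as pd
import pytest

from radres.simulate import SyntheticConfig


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Down-scaled study: full design, 40-gene chip, fast to generate."""
    return SyntheticConfig.from_calibration(11, n_genes=40, n_probes=60)


@pytest.fixture()
def probe_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": ["p1", "p2", "p3", "p1", "p2", "p3"],
            "gene_id": ["A", "A", "B", "A", "A", "B"],
            "sample_id": ["s1"] * 3 + ["s2"] * 3,
            "signal": [4.0, 9.0, 5.0, 2.0, 8.0, 3.0],
        }
    )


@pytest.fixture()
def control_frame() -> pd.DataFrame:
    """One gene whose controls are {8,9,10,11,12}; two case samples."""
    return pd.DataFrame(
        [[13.5, 13.0, 8.0, 9.0, 10.0, 11.0, 12.0]],
        index=["g1"],
        columns=["case_hi", "case_lo", "c1", "c2", "c3", "c4", "c5"],
    )


def make_foci_frame(groups: dict, n_cells: int = 50, seed: int = 0) -> pd.DataFrame:
    """Poisson foci table; ``groups`` maps lineage -> (mean, n_experiments)."""
    rng = np.random.default_rng(seed)
    rows = []
    for lineage, (mean, n_exp) in groups.items():
        for exp in range(1, n_exp + 1):
            counts = rng.poisson(mean, n_cells)
            for i, c in enumerate(counts):
                rows.append(("CL", lineage, True, False, exp, i + 1, int(c), int(c)))
    return pd.DataFrame(
        rows,
        columns=[
            "cell_line", "lineage", "irradiated", "washout",
            "experiment", "cell_index", "h2ax_count", "patm_count",
        ],
    )
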