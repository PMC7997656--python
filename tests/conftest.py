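import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from getmap.reference_panel import CpGSite, TissueMethylome
from getmap.simulation import build_panel_and_mask

DENOM = 10_000  # count denominator giving ~1e-4 density resolution


def methylomes_from_rows(rows, tissues=None, denom=DENOM):
    """Build one TissueMethylome per column from a site x tissue density
    table (list of per-site density tuples)."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n_tissues = rows.shape[1]
    if tissues is None:
        tissues = [f"t{k}" for k in range(n_tissues)]
    sites = [CpGSite("chr1", 100 + 2 * i) for i in range(len(rows))]
    return [
        TissueMethylome(
            tissue=tissues[k],
            sites={
                s: (round(rows[i, k] * denom), denom) for i, s in enumerate(sites)
            },
        )
        for k in range(n_tissues)
    ]


@pytest.fixture(scope="session")
def small_panel():
    """A small synthetic 5-tissue panel with marker selection applied."""
    methylomes, mask = build_panel_and_mask(
        n_sites=2_000, marker_fraction=0.3, seed=7
    )
    return methylomes, mask
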