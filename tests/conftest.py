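import numpy as np
import pandas as pd
import pytest

from tcrdyn.simulate import SimConfig, simulate_cohort
from tcrdyn.pipeline import cohort_cells


def make_contigs(rows):
    """Contig frame from (barcode, locus, v, j, c, nt, aa, umis) tuples."""
    return pd.DataFrame(rows, columns=[
        "barcode", "locus", "v_call", "j_call", "c_call",
        "cdr3_nt", "cdr3_aa", "umis"]).assign(productive=True)


@pytest.fixture(scope="session")
def small_cohort_cells():
    """Filtered joined cells for a small (fast) default-dynamics cohort."""
    cfg = SimConfig(seed=11, n_patients=3, cells_per_sample=300)
    return cohort_cells(simulate_cohort(cfg))


@pytest.fixture(scope="session")
def default_cohort_cells():
    """One full default cohort (5 patients, 1500-3500 cells/sample)."""
    return cohort_cells(simulate_cohort(SimConfig(seed=5)))
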