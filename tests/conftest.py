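import numpy as np
import pandas as pd
import pytest

from oasubtypes.qc import run_qc
from oasubtypes.simulate import CohortConfig, generate_cohort, \
    generate_genesets, generate_lr_database

# One moderately sized cohort shared (read-only) across the suite: 60 OA
# patients, 4 planted subtypes at the default uneven proportions, planted
# markers and crosstalk, 4 controls.
SMALL = dict(n_patients=60, n_genes=1500, n_lr_pairs=150, seed=11)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(**SMALL)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_lr(small_config):
    return generate_lr_database(small_config)


@pytest.fixture(scope="session")
def small_genesets(small_config):
    return generate_genesets(small_config)


@pytest.fixture(scope="session")
def qc_expr(small_cohort):
    """Post-QC cartilage CPM (OA samples) plus true subtype labels per sample."""
    counts, meta, truth = small_cohort
    expr_oa, expr_ctrl = run_qc(counts["cartilage"], meta)
    tru = pd.Series(truth.patient_subtype)
    labels = pd.Series([tru[c.split("_")[0]] for c in expr_oa.columns],
                       index=expr_oa.columns, name="subtype")
    return expr_oa, expr_ctrl, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
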