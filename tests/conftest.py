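import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from moma.io import ExpressionMatrix, TUMOUR, NON_MALIGNANT
from moma.simulate import SimConfig, generate_cohort


def make_expression(values: dict, roles: dict, pairing=None) -> ExpressionMatrix:
    """Small helper: build an ExpressionMatrix from plain dicts.

    ``values`` maps feature id → list of abundances ordered like ``roles``.
    """
    samples = list(roles)
    df = pd.DataFrame(values, index=samples).T
    role = pd.Series({s: (TUMOUR if roles[s] == "T" else NON_MALIGNANT) for s in samples})
    return ExpressionMatrix(values=df, sample_role=role, pairing=pairing)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact but complete synthetic cohort with strong planted effects."""
    cfg = SimConfig(
        seed=7,
        n_tumour=60,
        n_normal=20,
        n_pairs=15,
        expr_shift_log2=4.0,
        delta_beta_effect=-0.3,
        mirna_down_shift_sd=4.0,
        hazard_log_hr_per_point=0.4,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    from moma.simulate import write_cohort

    out = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, out)
    return out
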