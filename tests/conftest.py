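import numpy as np
import pandas as pd
import pytest

import cerebgrad as cg
from cerebgrad.synth import records_to_frame


@pytest.fixture(scope="session")
def small_cfg():
    return cg.CohortConfig(n_subjects=24, n_voxels=48, n_volumes=80, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    records, bolds, motions, volumes, truth = cg.generate_cohort(small_cfg)
    return {
        "records": records,
        "bolds": bolds,
        "motions": motions,
        "volumes": volumes,
        "truth": truth,
        "subjects": records_to_frame(records),
        "config": small_cfg,
    }


@pytest.fixture(scope="session")
def small_group(small_cohort):
    vectors = [
        cg.vectorize_upper(cg.fc_matrix(b), subject_id=b.subject_id)
        for b in small_cohort["bolds"]
    ]
    return cg.assemble_group_matrix(vectors)


def brute_force_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson r, independent of numpy.corrcoef."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def brute_force_bh(p):
    """Step-up BH on a plain python list, by the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = min(running, 1.0)
    return adj
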