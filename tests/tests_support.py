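"""Shared helpers for the test suite and the acceptance script."""

import numpy as np
import pandas as pd

from nmoa import GroundTruth
from nmoa.observer import _CELLS, dprime_to_probabilities
from nmoa.psychometrics import dprime


def simulate_cells(truth: GroundTruth, coherences, trials_per_cell: int,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Binomial-noise d' table straight from ground-truth curves.

    The per-trial noise model is the virtual observer's (independent
    Bernoulli responses from the equal-variance probabilities); drawing the
    cell counts directly just skips the trial bookkeeping.
    """
    n_half = trials_per_cell // 2
    rows = []
    for (ct, val) in _CELLS:
        for c in coherences:
            d_true = float(truth.dprime_at(ct, val, c))
            p_cw_cw, p_cw_ccw = dprime_to_probabilities(d_true, truth.bias)
            hits = rng.binomial(n_half, p_cw_cw)
            fas = rng.binomial(n_half, p_cw_ccw)
            rows.append((ct, val, float(c), dprime(hits, fas, n_half, n_half)))
    return pd.DataFrame(rows, columns=["cue_type", "validity", "coherence", "dprime"])
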