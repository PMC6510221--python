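"""Abundance-weighted Raup-Crick (RC_bray).

For each sample pair the observed Bray-Curtis dissimilarity is compared to
the distribution obtained by repeatedly re-assembling both samples under
the richness- and abundance-preserving null of :mod:`assemblyscope.beta`.
The fraction of null values below the observation (ties counted half) is
rescaled to [-1, +1]: values near +1 mean the pair is more dissimilar than
chance (dispersal limitation when selection is weak), near -1 more similar
than chance (homogenizing dispersal).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .beta import NullModelConfig, null_bray_curtis_distribution
from .io import OtuTable

_TIE_TOL = 1e-10


def rc_bray(table: OtuTable, config: NullModelConfig) -> pd.DataFrame:
    """Abundance-weighted Raup-Crick metric for every sample pair.

    Returns one row per pair with the observed Bray-Curtis value, the
    fraction of null values below it (ties half-weighted), and
    ``rc_bray = 2 * (frac - 0.5)`` in [-1, +1].
    """
    pairs, obs, null = null_bray_curtis_distribution(table, config)
    diff = null - obs[None, :]
    below = (diff < -_TIE_TOL).sum(axis=0)
    equal = (np.abs(diff) <= _TIE_TOL).sum(axis=0)
    frac = (below + 0.5 * equal) / config.reps
    out = pairs.copy()
    out["bc_observed"] = obs
    out["frac_null_below"] = frac
    out["rc_bray"] = 2.0 * (frac - 0.5)
    return out
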