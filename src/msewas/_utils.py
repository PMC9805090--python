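"""Shared numeric helpers: beta/M transforms and clipping."""

from __future__ import annotations

import numpy as np

#: beta values are clipped into [EPS, 1-EPS] before the logit so M stays finite
EPS = 1e-6


def clip_beta(beta):
    """Clip beta values into the open interval (0, 1) at tolerance EPS."""
    return np.clip(beta, EPS, 1.0 - EPS)


def beta_to_m(beta):
    """M = log2(beta / (1 - beta)), the logit2 transform of a beta value.

    Accepts scalars, arrays, Series or DataFrames; values outside [0, 1]
    raise ValueError. Values are clipped to [EPS, 1-EPS] first so the
    transform is finite; on the clipped domain it is a bijection.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr)):
        raise ValueError("beta values must lie in [0, 1]")
    clipped = clip_beta(beta)
    return np.log2(clipped / (1.0 - clipped))


def m_to_beta(m):
    """Inverse of beta_to_m: beta = 2^M / (2^M + 1).

    Preserves pandas containers (Series/DataFrame in, same type out).
    """
    p = np.power(2.0, m)
    return p / (p + 1.0)
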