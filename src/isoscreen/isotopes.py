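"""Stable-isotope delta notation.

Isotope-ratio mass spectrometry reports the abundance ratio of the heavy to
the light isotope (15N/14N, 13C/12C) relative to an international standard,
expressed in per-mil (‰) delta notation:

    delta = (R_sample / R_standard - 1) * 1000

Synthetic N fertilizer carries a delta15N close to atmospheric N2 (0 ‰),
while organic amendments (manure, compost, protein meals) are 15N-enriched,
which is what makes delta15N informative for production-system screening.
"""

from __future__ import annotations

import numpy as np

__all__ = ["compute_delta"]


def compute_delta(ratio_sample, ratio_standard):
    """Convert isotope abundance ratios to a per-mil delta value.

    Parameters
    ----------
    ratio_sample, ratio_standard : float or array-like
        Heavy/light isotope abundance ratios; must be strictly positive.

    Returns
    -------
    float or ndarray
        ``(ratio_sample / ratio_standard - 1) * 1000`` in ‰.
    """
    rs = np.asarray(ratio_sample, dtype=float)
    rstd = np.asarray(ratio_standard, dtype=float)
    if np.any(rs <= 0) or np.any(rstd <= 0):
        raise ValueError("isotope abundance ratios must be strictly positive")
    out = (rs / rstd - 1.0) * 1000.0
    if np.isscalar(ratio_sample) and np.isscalar(ratio_standard):
        return float(out)
    return out
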