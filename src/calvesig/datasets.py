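"""Small reference datasets bundled with the package.

The remaining-hours matrix below is the published summary of a six-cow
Holter feasibility study: for each cow (columns) and each indicator computed
on the STL trend of its R-R series (rows), the hours from the indicator's
peak signal to the observed calving moment, together with the indicator's
value at the peak.  Missing cells mark indicators that produced no signal
for that animal (the RSI of a cow whose trend declined monotonically
throughout the recording, and the SMA peak that could not be assigned for
the same animal).

These printed values are inputs: the underlying recordings are not public,
so the matrix is what the evaluation statistics (marginal means, paired
indicator contrasts, coefficients of variation) are recomputed from.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SUBJECTS",
    "INDICATORS",
    "remaining_hours_matrix",
    "indicator_value_matrix",
]

SUBJECTS = ["h021", "h045", "h057", "h055", "h058", "h886"]
INDICATORS = ["SMA", "MAD", "MACD", "RSI"]

_HOURS = {
    "SMA": [53.0, 69.5, 61.0, np.nan, 42.5, 44.5],
    "MAD": [56.0, 76.0, 66.0, 43.0, 47.5, 63.5],
    "MACD": [53.5, 72.0, 62.0, 42.5, 43.5, 59.5],
    "RSI": [56.0, 72.0, 62.0, np.nan, 43.5, 45.0],
}

_VALUES = {
    "SMA": [734.2, 744.2, 578.2, np.nan, 588.6, 626.1],
    "MAD": [0.3, 0.2, 0.1, -0.3, 0.3, 0.4],
    "MACD": [0.0, 0.2, 0.1, -0.4, 0.1, 0.4],
    "RSI": [72.2, 95.2, 86.5, np.nan, 67.4, 99.5],
}


def remaining_hours_matrix() -> pd.DataFrame:
    """Indicator x subject matrix of remaining hours to calving (NaN = no signal)."""
    return pd.DataFrame(_HOURS, index=SUBJECTS).T.loc[INDICATORS]


def indicator_value_matrix() -> pd.DataFrame:
    """Indicator x subject matrix of indicator values at the peak signal.

    SMA values are in milliseconds; MAD and MACD are percent deviations;
    RSI is the 0-100 index.
    """
    return pd.DataFrame(_VALUES, index=SUBJECTS).T.loc[INDICATORS]
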