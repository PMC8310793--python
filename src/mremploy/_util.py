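"""Small shared numerical helpers."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

# Normal 97.5% quantile to the precision used for all 95% CIs, so that
# CI <-> SE conversions round-trip exactly.
Z95 = 1.959964


def design_frame(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    """Regression design columns: numeric passed through, categorical/object
    expanded to dummies with the most frequent level as reference."""
    parts: dict[str, np.ndarray] = {}
    for c in cols:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            ref = col.value_counts().idxmax()
            for lev in sorted(x for x in col.unique() if x != ref):
                parts[f"{c}[{lev}]"] = (col == lev).to_numpy(float)
        else:
            parts[c] = col.to_numpy(float)
    return pd.DataFrame(parts, index=df.index)
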