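"""Cross-condition statistics: pairwise t-tests with Holm-Sidak correction."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["holm_sidak", "compare_conditions"]


def holm_sidak(pvals) -> np.ndarray:
    """Step-down Sidak-adjusted p-values.

    Sorted ascending, ``p_adj(i) = 1 - (1 - p_(i))^(m - i + 1)`` with
    monotonicity enforced, then mapped back to the input order.
    """
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(pvals, method="holm-sidak")
    return p_adj


def compare_conditions(values: dict, pairs=None) -> pd.DataFrame:
    """Two-sided t-tests between conditions, Holm-Sidak corrected.

    ``values`` maps a condition name to its replicate measurements (e.g.
    per-replicate cycle free energies).  Pairs with fewer than two
    replicates on either side are skipped with a warning.
    """
    if pairs is None:
        names = list(values)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in pairs:
        xa, xb = np.asarray(values[a], float), np.asarray(values[b], float)
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(f"pair ({a}, {b}) skipped: fewer than 2 replicates",
                          stacklevel=2)
            continue
        t, p = sps.ttest_ind(xa, xb)
        rows.append({"condition_a": a, "condition_b": b,
                     "t": float(t), "p_raw": float(p)})
    table = pd.DataFrame(rows, columns=["condition_a", "condition_b", "t", "p_raw"])
    if len(table):
        table["p_adj"] = holm_sidak(table["p_raw"].to_numpy())
    else:
        table["p_adj"] = []
    return table
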