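"""Spearman correlation of metabolite levels with a clinical score.

Correlates the discriminating metabolites with the disease-activity score
(DAPSA) of the patient group: midrank Spearman r, a two-sided p-value
(exact permutation for n <= 10, t-approximation above), and a 95% CI from
the Fisher z-transform with the 1.06/(n-3) variance commonly used for
Spearman's statistic.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["spearman", "correlate_panel"]


def _exact_p(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided permutation p for the rank correlation, by enumeration.

    Enumerates all n! orderings of y's ranks in chunks; feasible to n=10.
    """
    n = rx.size
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    observed = abs(float(rx_c @ ry_c) / denom)
    count = 0
    total = 0
    chunk = []
    for perm in permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            P = ry_c[np.array(chunk)]
            count += int(np.sum(np.abs(P @ rx_c) / denom >= observed - 1e-12))
            total += len(chunk)
            chunk = []
    if chunk:
        P = ry_c[np.array(chunk)]
        count += int(np.sum(np.abs(P @ rx_c) / denom >= observed - 1e-12))
        total += len(chunk)
    return count / total


def spearman(x, y, level: float = 0.95):
    """Spearman correlation with CI and two-sided p.

    r is the Pearson correlation of midranks.  p is exact (full
    permutation enumeration) for n <= 10, else the t-approximation.  The
    CI is tanh(atanh(r) -/+ z*sqrt(1.06/(n-3))).

    Returns (r, p, (lo, hi)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input: rank correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _exact_p(rx, ry)
    else:
        # t-approximation on r with n-2 degrees of freedom
        tstat = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
    z = stats.norm.ppf(0.5 + level / 2.0)
    if abs(r) >= 1.0:
        ci = (r, r)
    else:
        se = np.sqrt(1.06 / (n - 3))
        zr = np.arctanh(r)
        ci = (float(np.tanh(zr - z * se)), float(np.tanh(zr + z * se)))
    return r, min(1.0, p), ci


def correlate_panel(conc: pd.DataFrame, cohort: pd.DataFrame,
                    metabolites, score_col: str = "dapsa",
                    group: str = "PsA") -> pd.DataFrame:
    """Correlate each listed metabolite with the clinical score.

    Restricted to rows of ``group`` with a non-missing score; one output
    row per metabolite, in the given order.
    """
    missing = [m for m in metabolites if m not in conc.columns]
    if missing:
        raise ValueError(f"metabolites absent from table: {missing}")
    mask = (cohort["group"] == group) & cohort[score_col].notna()
    if not mask.any():
        raise ValueError(f"no {group} rows with a {score_col} score")
    idx = cohort.index[mask]
    score = cohort.loc[idx, score_col].to_numpy(float)
    rows = []
    for m in metabolites:
        r, p, (lo, hi) = spearman(conc.loc[idx, m].to_numpy(float), score)
        rows.append({"metabolite": m, "r": r, "ci_lo": lo, "ci_hi": hi,
                     "p": p, "n": idx.size})
    return pd.DataFrame(rows).set_index("metabolite")
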