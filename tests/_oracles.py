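"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: rotations come
from scipy's Rotation.align_vectors, ANOVA mean squares from
statsmodels' anova_lm, and the Pearson test from raw sums.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def _normalize(config: np.ndarray) -> np.ndarray:
    c = config - config.mean(axis=0)
    return c / np.sqrt(np.sum(c**2))


def bruteforce_gpa_ss(
    configs: list[np.ndarray],
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-14,
) -> float:
    """Best total Procrustes sum of squares found by alternating
    minimization from random restarts.

    Each restart seeds the reference with a randomly rotated input
    configuration, then alternates: (a) rotate every unit-size centred
    configuration onto the reference with scipy's align_vectors, (b)
    replace the reference by the renormalized average; until the
    objective stalls.  Returns the smallest objective over restarts.
    """
    arrs = [_normalize(np.asarray(c, dtype=float)) for c in configs]
    rng = np.random.default_rng(seed)
    best = np.inf
    for restart in range(n_restarts):
        start = arrs[restart % len(arrs)]
        mean = start @ Rotation.random(rng=rng).as_matrix()
        prev = np.inf
        for _ in range(max_iter):
            rotated = []
            for a in arrs:
                rot, _ = Rotation.align_vectors(mean, a)
                rotated.append(rot.apply(a))
            new_mean = _normalize(np.mean(rotated, axis=0))
            obj = float(sum(np.sum((r - new_mean) ** 2) for r in rotated))
            mean = new_mean
            if prev - obj < tol:
                break
            prev = obj
        best = min(best, obj)
    return best


def anova_mean_squares(groups, values) -> tuple[float, float]:
    """(MS_among, MS_within) from statsmodels' one-way ANOVA table."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"g": np.asarray(groups).astype(str), "v": np.asarray(values, dtype=float)})
    fit = ols("v ~ C(g)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    ms_among = table.loc["C(g)", "sum_sq"] / table.loc["C(g)", "df"]
    ms_within = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
    return float(ms_among), float(ms_within)


def pearson_from_sums(x, y) -> tuple[float, float, float]:
    """(r, t, two-sided p) computed from raw sums and the t CDF."""
    from scipy import stats as st

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
    df = n - 2
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * st.t.sf(abs(t), df)
    return float(r), float(t), float(p)
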