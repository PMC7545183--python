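"""Independent reference implementations used only as test oracles.

These are deliberately plain, loop-based transcriptions kept separate from
the library's vectorized code paths.
"""

import numpy as np


def wc_components_loop(dosages1, dosages2):
    """Weir & Cockerham (1984) two-population variance components for one
    diploid site, transcribed directly from the estimator definitions.

    Returns (a, b, c, usable).
    """
    d1 = [d for d in dosages1 if d != -1]
    d2 = [d for d in dosages2 if d != -1]
    n1, n2 = len(d1), len(d2)
    if n1 < 1 or n2 < 1 or n1 + n2 < 3:
        return 0.0, 0.0, 0.0, False
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    p1 = sum(d1) / (2 * n1)
    p2 = sum(d2) / (2 * n2)
    h1 = sum(1 for d in d1 if d == 1) / n1
    h2 = sum(1 for d in d2 if d == 1) / n2
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    if (pbar == 0.0 or pbar == 1.0) and hbar == 0.0:
        return 0.0, 0.0, 0.0, False
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c, True


def n50_brute(lengths, x=50):
    """Nx by explicit cumulative walk over descending lengths."""
    lens = sorted(lengths, reverse=True)
    total = sum(lens)
    cum = 0
    for ln in lens:
        cum += ln
        if cum >= x / 100.0 * total:
            return ln
    raise AssertionError("unreachable")


def ols_marker_pvalue(x, y):
    """Two-sided p-value for the marker slope in y ~ 1 + x by the textbook
    OLS t-test."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    t = beta[1] / se
    return 2.0 * stats.t.sf(abs(t), n - 2)
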