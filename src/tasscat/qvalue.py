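"""Storey q-values for false discovery rate control.

The q-value of a test is the minimum FDR at which it would be called
significant.  Unlike Benjamini-Hochberg, Storey's procedure estimates the
proportion of true nulls pi0 from the p-value histogram, which makes it
less conservative when many tests are non-null.
"""

from __future__ import annotations

import numpy as np

__all__ = ["estimate_pi0", "storey_qvalues"]


def estimate_pi0(pvalues, lambdas=None, method: str = "smoother") -> float:
    """Estimate the proportion of true null hypotheses.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) is computed over a grid
    of lambda values; with ``method="smoother"`` a cubic polynomial is fit
    to pi0(lambda) and evaluated at the largest lambda (the histogram's
    right tail, least contaminated by alternatives).  ``method="fixed"``
    uses the median of the grid estimates.  The result is clipped to
    (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        raise ValueError("empty p-value array")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    # Discrete or bounded test statistics can leave the upper tail of the
    # p-value distribution empty (max attainable p < 1); lambda points at or
    # beyond the largest observed p carry no information about pi0 and drag
    # the smoother to zero.  Those points are dropped and the tail width is
    # measured relative to the attainable range [0, max(p)], which reduces
    # to the classic estimator when p-values span [0, 1].
    p_max = float(p.max())
    keep = lambdas < p_max
    lambdas = lambdas[keep] if keep.any() else lambdas[:1]

    def _pi0_at(lam):
        width = max(p_max - lam, 1e-8) / max(p_max, 1e-8)
        return (p > lam).sum() / (m * width)

    if lambdas.size == 1:
        return float(min(max(_pi0_at(lambdas[0]), 1.0 / m), 1.0))
    pi0_grid = np.array([_pi0_at(lam) for lam in lambdas])
    if lambdas.size < 4:
        method = "fixed"    # too few points for a stable cubic smoother
    if method == "smoother":
        coef = np.polyfit(lambdas, pi0_grid, deg=3)
        pi0 = float(np.polyval(coef, lambdas.max()))
    elif method == "fixed":
        pi0 = float(np.median(pi0_grid))
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(pvalues, pi0: float | None = None, lambdas=None) -> np.ndarray:
    """Convert p-values to Storey q-values.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the sorted p-values, so
    q is monotone non-decreasing in p.  ``pi0`` may be supplied directly
    (e.g. 1.0 reproduces Benjamini-Hochberg); otherwise it is estimated
    from the data via :func:`estimate_pi0`.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p, lambdas=lambdas)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
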