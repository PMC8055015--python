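"""Zero-inflated Poisson significance model for miSS read counts.

The split-read count of a miSS depends strongly on the local coverage, for
which the count of the corresponding maSS is a natural proxy.  Per tissue,
r_miSS is modelled as zero-inflated Poisson with

    lambda(r_maSS) = a0 * r_maSS ** a1          (power-law mean)
    pi(r_maSS)     = logit^-1(b0 + b1 * r_maSS) (structural-zero probability)

and each observed miSS count receives the upper-tail probability

    P = 1 - (CDF_Poisson(r_miSS; lambda) * (1 - pi) + pi)

under the fitted null.  Q-values over the flattened miSS x tissue matrix
plus a minimum relative usage (phi > 0.05) define the significantly
expressed miSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.discrete.count_model import ZeroInflatedPoisson

from tasscat.catalog import compute_phi
from tasscat.qvalue import storey_qvalues

__all__ = ["ZipFit", "fit_zip", "zip_pvalue", "significance_table",
           "call_significant"]


@dataclass
class ZipFit:
    """Fitted per-tissue ZIP parameters.

    a0, a1 parameterize the power-law mean lambda = a0 * r_maSS^a1;
    b0, b1 the logistic zero-inflation pi = logit^-1(b0 + b1 * r_maSS).
    """

    tissue: str | None
    a0: float
    a1: float
    b0: float
    b1: float
    n_obs: int
    converged: bool

    def lambda_hat(self, r_mass):
        r_mass = np.asarray(r_mass, dtype=float)
        return self.a0 * r_mass ** self.a1

    def pi_hat(self, r_mass):
        r_mass = np.asarray(r_mass, dtype=float)
        return expit(self.b0 + self.b1 * r_mass)


def fit_zip(r_miss, r_mass, tissue=None, min_pairs: int = 50) -> ZipFit:
    """Maximum-likelihood ZIP fit of miSS counts conditional on maSS counts.

    Pairs with ``r_mass == 0`` are excluded: the covariate log(r_maSS) is
    singular there and lambda is undefined for a1 < 0.  A constant r_maSS
    leaves a1 unidentifiable and raises.  Non-convergence is reported via
    ``converged=False`` (downstream significance calls should be suppressed
    for that tissue).

    Starting values come from a Poisson log-log regression for (a0, a1)
    and from the excess-zero fraction for (b0, b1).
    """
    r_miss = np.asarray(r_miss, dtype=float)
    r_mass = np.asarray(r_mass, dtype=float)
    keep = r_mass > 0
    r_miss, r_mass = r_miss[keep], r_mass[keep]
    n = r_miss.size
    if n < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs with r_mass > 0, got {n}")
    if np.unique(r_mass).size < 2:
        raise ValueError("constant r_maSS: a1 is unidentifiable")

    log_mass = np.log(r_mass)
    exog = np.column_stack([np.ones(n), log_mass])
    exog_infl = np.column_stack([np.ones(n), r_mass])

    # Poisson start for the count part; moment start for the inflation part.
    import statsmodels.api as sm
    pois = sm.GLM(r_miss, exog, family=sm.families.Poisson()).fit()
    lam0 = pois.predict(exog)
    excess = max(float(np.mean(r_miss == 0) - np.mean(np.exp(-lam0))), 0.01)
    excess = min(excess, 0.95)
    start = np.r_[np.log(excess / (1 - excess)), 0.0, pois.params]

    model = ZeroInflatedPoisson(r_miss, exog, exog_infl=exog_infl,
                                inflation="logit")
    converged = False
    res = None
    for method in ("bfgs", "lbfgs", "nm"):
        try:
            res = model.fit(start_params=start, method=method, maxiter=2000,
                            disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            continue
        if converged:
            break
    if res is None:
        raise RuntimeError("ZIP optimisation failed to produce a fit")
    b0, b1, const, a1 = (float(res.params[i]) for i in range(4))
    return ZipFit(tissue, float(np.exp(const)), a1, b0, b1, n, converged)


def zip_pvalue(r_miss, lambda_hat, pi_hat, inclusive_tail: bool = False):
    """Upper-tail probability of a miSS count under the fitted ZIP null.

    P = 1 - (CDF_Poisson(r; lambda) * (1 - pi) + pi), i.e. the probability
    that a ZIP draw strictly exceeds the observed count.  With
    ``inclusive_tail=True`` the CDF is evaluated at r - 1, giving the
    conventional P(X >= r) instead.  Accepts scalars or arrays.
    """
    r = np.asarray(r_miss, dtype=float)
    lam = np.asarray(lambda_hat, dtype=float)
    pi = np.asarray(pi_hat, dtype=float)
    if (lam <= 0).any():
        raise ValueError("lambda must be positive")
    if ((pi < 0) | (pi > 1)).any():
        raise ValueError("pi must lie in [0, 1]")
    k = r - 1 if inclusive_tail else r
    p = 1.0 - (stats.poisson.cdf(k, lam) * (1.0 - pi) + pi)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def significance_table(pairs: pd.DataFrame, fits: dict,
                       inclusive_tail: bool = False) -> pd.DataFrame:
    """Per-(miSS, tissue) significance calls from per-tissue ZIP fits.

    Parameters
    ----------
    pairs : DataFrame with columns ``miss_id, tissue, r_miss, r_mass``.
    fits : mapping tissue -> ZipFit.

    Returns the input with ``phi, p, q`` columns added.  Pairs with
    ``r_mass == 0``, with no fit for their tissue, or with a non-converged
    fit receive no P-value (NaN) and are excluded from the q-value
    computation.
    """
    out = pairs.copy()
    out["phi"] = compute_phi(out["r_miss"].to_numpy(),
                             out["r_mass"].to_numpy())
    p = np.full(len(out), np.nan)
    for tissue, idx in out.groupby("tissue").groups.items():
        fit = fits.get(tissue)
        if fit is None or not fit.converged:
            continue
        sub = out.loc[idx]
        ok = sub["r_mass"].to_numpy() > 0
        r_mass = sub["r_mass"].to_numpy()[ok]
        r_miss = sub["r_miss"].to_numpy()[ok]
        vals = zip_pvalue(r_miss, fit.lambda_hat(r_mass), fit.pi_hat(r_mass),
                          inclusive_tail=inclusive_tail)
        loc = np.asarray(idx)[ok]
        p[out.index.get_indexer(loc)] = vals
    out["p"] = p
    out["q"] = np.nan
    have_p = ~np.isnan(p)
    if have_p.any():
        out.loc[have_p, "q"] = storey_qvalues(p[have_p])
    return out


def call_significant(calls: pd.DataFrame, q_thresh: float = 0.05,
                     phi_thresh: float = 0.05) -> set:
    """miSS significant in at least one tissue (q < q_thresh and phi > phi_thresh)."""
    hit = calls[(calls["q"] < q_thresh) & (calls["phi"] > phi_thresh)]
    return set(hit["miss_id"])
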