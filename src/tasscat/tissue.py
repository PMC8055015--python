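"""Tissue-specific (and cell-type-specific) miSS calls.

For each significant miSS the per-sample miSS count is regressed on the
maSS count through the origin with a tissue indicator interaction,

    r_miSS = a0 * r_maSS + a_t * D_t * r_maSS,

one one-vs-rest regression per tissue (a single joint model with dummies
for every tissue is perfectly collinear with the shared slope).  The slope
deviation a_t translates into the relative-usage deviation

    phi_bar   = a0 / (1 + a0)
    phi_t     = (a0 + a_t) / (1 + a0 + a_t)
    dphi_t    = a_t / ((1 + a0 + a_t) * (1 + a0))  ==  phi_t - phi_bar

and a miSS is tissue-specific when a_t is significant (q < 0.05) and the
deviation is substantial (|dphi_t| > 0.05).  The same machinery serves
cell-type and tissue-of-origin groupings by swapping the grouping label.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from tasscat.qvalue import storey_qvalues

__all__ = ["fit_tissue_model", "fit_all_tissues", "delta_phi",
           "call_specific", "becomes_mass", "phi_with_min_reads",
           "profile_similarity"]


def fit_tissue_model(samples: pd.DataFrame, target_tissue: str,
                     group_col: str = "tissue"):
    """One-vs-rest no-intercept regression of r_miss on r_mass.

    Parameters
    ----------
    samples : DataFrame with columns ``r_miss, r_mass`` and ``group_col``.
    target_tissue : the tissue whose deviation slope a_t is estimated.

    Returns
    -------
    (a0, a_t, p_value, se_t) with a two-tailed t-test p for a_t.
    """
    groups = samples[group_col]
    if target_tissue not in set(groups):
        raise ValueError(f"tissue {target_tissue!r} absent from samples")
    if groups.nunique() < 2:
        raise ValueError("need at least two tissues")
    r_mass = samples["r_mass"].to_numpy(dtype=float)
    r_miss = samples["r_miss"].to_numpy(dtype=float)
    d = (groups == target_tissue).to_numpy(dtype=float)
    X = np.column_stack([r_mass, d * r_mass])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("singular design (no maSS reads in a group?)")
    res = sm.OLS(r_miss, X).fit()
    return (float(res.params[0]), float(res.params[1]),
            float(res.pvalues[1]), float(res.bse[1]))


def fit_all_tissues(samples: pd.DataFrame, group_col: str = "tissue",
                    min_target_samples: int = 3) -> pd.DataFrame:
    """Deviation slopes for every tissue of one miSS.

    Tissues with fewer than ``min_target_samples`` samples are skipped.
    Returns a DataFrame with columns ``tissue, a0, a_t, p, se``.
    """
    rows = []
    for tissue, sub in samples.groupby(group_col):
        if len(sub) < min_target_samples:
            continue
        a0, a_t, p, se = fit_tissue_model(samples, tissue,
                                          group_col=group_col)
        rows.append({"tissue": tissue, "a0": a0, "a_t": a_t, "p": p,
                     "se": se})
    return pd.DataFrame(rows)


def delta_phi(a0: float, a_t: float):
    """Tissue-average phi, tissue phi, and their difference from the slopes.

    Undefined (NaN triple) when a denominator 1 + a0 or 1 + a0 + a_t is
    non-positive, which corresponds to an inadmissible negative usage.
    """
    if 1 + a0 <= 0 or 1 + a0 + a_t <= 0:
        return float("nan"), float("nan"), float("nan")
    phi_bar = a0 / (1 + a0)
    phi_t = (a0 + a_t) / (1 + a0 + a_t)
    dphi = a_t / ((1 + a0 + a_t) * (1 + a0))
    return phi_bar, phi_t, dphi


def call_specific(fits: pd.DataFrame, q_thresh: float = 0.05,
                  dphi_thresh: float = 0.05) -> pd.DataFrame:
    """Tissue-specificity calls over a miSS x tissue table of slope fits.

    ``fits`` must have columns ``miss_id, tissue, a0, a_t, p``.  Q-values
    are computed over the flattened table (restricted to the miSS present,
    i.e. already filtered to significant miSS upstream).  A (miSS, tissue)
    pair is specific iff q < q_thresh and |dphi_t| > dphi_thresh; the
    direction is up for a_t > 0 and down for a_t < 0.
    """
    out = fits.copy()
    out["q"] = storey_qvalues(out["p"].to_numpy(dtype=float))
    trip = [delta_phi(a0, a_t)
            for a0, a_t in zip(out["a0"], out["a_t"])]
    out["dphi"] = [t[2] for t in trip]
    out["direction"] = np.where(out["a_t"] > 0, "up", "down")
    out["specific"] = ((out["q"] < q_thresh)
                       & (out["dphi"].abs() > dphi_thresh)
                       & out["dphi"].notna())
    return out


def becomes_mass(phi_t) -> bool:
    """True iff the miSS overtakes its maSS (phi > 0.5) in some tissue."""
    phi_t = np.asarray(list(phi_t) if not isinstance(phi_t, np.ndarray)
                       else phi_t, dtype=float)
    return bool((phi_t > 0.5).any())


def phi_with_min_reads(r_miss, r_mass, min_reads: int = 20):
    """Per-sample phi, zeroed where both counts are weak.

    phi is kept only when at least one of r_miSS and r_maSS exceeds
    ``min_reads``; otherwise it is substituted with zero (profiles built
    from a handful of reads are dominated by sampling noise).
    """
    r_miss = np.asarray(r_miss, dtype=float)
    r_mass = np.asarray(r_mass, dtype=float)
    denom = r_miss + r_mass
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, r_miss / np.where(denom > 0, denom, 1), 0.0)
    ok = (r_miss > min_reads) | (r_mass > min_reads)
    return np.where(ok, phi, 0.0)


def profile_similarity(phi_matrix: pd.DataFrame, cell_types, tissues):
    """Pairwise Pearson similarity of miSS usage profiles between samples.

    Parameters
    ----------
    phi_matrix : DataFrame, samples x miSS, of per-sample phi values
        (already zeroed under the minimum-read rule).
    cell_types, tissues : per-sample labels aligned with the rows.

    Returns
    -------
    dict with the four pair categories mapping to arrays of Pearson r:
    ``same_cell_type_diff_tissue``, ``same_tissue_diff_cell_type``,
    ``same_both`` and ``diff_both``, plus ``mannwhitney_p``: the one-tailed
    Mann-Whitney P that same-cell-type/different-tissue pairs are more
    similar than same-tissue/different-cell-type pairs.
    """
    values = phi_matrix.to_numpy(dtype=float)
    cell_types = np.asarray(cell_types)
    tissues = np.asarray(tissues)
    n = values.shape[0]
    corr = np.corrcoef(values)
    cats = {"same_cell_type_diff_tissue": [],
            "same_tissue_diff_cell_type": [],
            "same_both": [], "diff_both": []}
    for i, j in combinations(range(n), 2):
        r = corr[i, j]
        same_ct = cell_types[i] == cell_types[j]
        same_ti = tissues[i] == tissues[j]
        if same_ct and same_ti:
            cats["same_both"].append(r)
        elif same_ct:
            cats["same_cell_type_diff_tissue"].append(r)
        elif same_ti:
            cats["same_tissue_diff_cell_type"].append(r)
        else:
            cats["diff_both"].append(r)
    out = {k: np.asarray(v) for k, v in cats.items()}
    a = out["same_cell_type_diff_tissue"]
    b = out["same_tissue_diff_cell_type"]
    if a.size and b.size:
        out["mannwhitney_p"] = float(
            stats.mannwhitneyu(a, b, alternative="greater").pvalue)
    else:
        out["mannwhitney_p"] = float("nan")
    return out
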