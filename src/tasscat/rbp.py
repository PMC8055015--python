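"""miSS-RBP regulatory triples.

A candidate regulatory event combines three observations about a minor
splice site (miSS), an RNA-binding protein (RBP) and a tissue:

- dphi_t:   tissue deviation of miSS usage (from the tissue dummy model);
- drbp_t:   tissue log2 fold change of the RBP's expression;
- dphi_kd:  miSS usage response to shRNA knockdown of the RBP.

If the RBP drives the tissue pattern, the tissue correlation must be
concordant with the knockdown-implied direction: e.g. a miSS up in a
tissue where the RBP is up should go down when the RBP is depleted.  This
holds exactly when the product of the three signs is -1 ("co-directed");
sign product +1 is "anti-directed".  An excess of co-directed triples, and
a higher co-directed fraction among triples backed by an eCLIP binding
peak near the miSS, are the module's two enrichment readouts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["filter_kd_pairs", "build_triples", "classify_direction",
           "direction_binomial_test", "merge_intervals", "filter_peaks",
           "eclip_support", "compare_oe_kd"]


def filter_kd_pairs(responses: pd.DataFrame, q_thresh: float = 0.05,
                    dphi_thresh: float = 0.05,
                    cell_lines=("K562", "HepG2")):
    """Significant, cell-line-concordant (RBP, miSS) knockdown pairs.

    ``responses`` has columns ``miss_id, rbp, cell_line, dphi_kd, q``.  A
    pair is kept iff in *both* cell lines q < q_thresh and
    |dphi_kd| > dphi_thresh, and the sign of dphi_kd agrees between the
    lines; significant pairs with discordant signs are excluded and
    reported.

    Returns
    -------
    (kept, discordant_fraction) where ``kept`` has columns
    ``miss_id, rbp, dphi_kd`` (dphi_kd averaged over the two lines) and
    the fraction is #discordant / #significant-in-both.
    """
    sig = responses[(responses["q"] < q_thresh)
                    & (responses["dphi_kd"].abs() > dphi_thresh)]
    wide = sig.pivot_table(index=["miss_id", "rbp"], columns="cell_line",
                           values="dphi_kd", aggfunc="first")
    missing = [cl for cl in cell_lines if cl not in wide.columns]
    for cl in missing:
        wide[cl] = np.nan
    both = wide.dropna(subset=list(cell_lines))
    if both.empty:
        return (pd.DataFrame(columns=["miss_id", "rbp", "dphi_kd"]), 0.0)
    a, b = (both[cl].to_numpy() for cl in cell_lines)
    concordant = np.sign(a) == np.sign(b)
    kept = both[concordant].copy()
    kept["dphi_kd"] = kept[list(cell_lines)].mean(axis=1)
    kept = kept.reset_index()[["miss_id", "rbp", "dphi_kd"]]
    discordant_fraction = float(1.0 - concordant.mean())
    return kept, discordant_fraction


def classify_direction(dphi_t: float, drbp_t: float, dphi_kd: float) -> str:
    """"co" iff the product of the three signs is -1, "anti" otherwise.

    All three deltas must be strictly nonzero (upstream thresholds
    guarantee this for real calls).
    """
    if dphi_t == 0 or drbp_t == 0 or dphi_kd == 0:
        raise ValueError("cannot sign a zero delta")
    product = np.sign(dphi_t) * np.sign(drbp_t) * np.sign(dphi_kd)
    return "co" if product == -1 else "anti"


def build_triples(specific_miss: pd.DataFrame, rbp_de: pd.DataFrame,
                  kd_pairs: pd.DataFrame) -> pd.DataFrame:
    """Inner-join miSS-tissue, RBP-tissue and RBP-miSS tables into triples.

    Parameters
    ----------
    specific_miss : columns ``miss_id, tissue, dphi_t`` (tissue-specific
        miSS calls).
    rbp_de : columns ``rbp, tissue, log2fc`` (tissue-specific RBPs).
    kd_pairs : columns ``miss_id, rbp, dphi_kd`` (concordant KD responses).

    Returns a DataFrame with one row per (miss_id, rbp, tissue) triple and
    a ``direction`` label.
    """
    merged = specific_miss.merge(rbp_de, on="tissue").merge(
        kd_pairs, on=["miss_id", "rbp"])
    if merged.empty:
        return merged.assign(direction=pd.Series(dtype=object))
    merged = merged[(merged["dphi_t"] != 0) & (merged["log2fc"] != 0)
                    & (merged["dphi_kd"] != 0)].copy()
    merged["direction"] = [
        classify_direction(a, b, c)
        for a, b, c in zip(merged["dphi_t"], merged["log2fc"],
                           merged["dphi_kd"])]
    return merged.reset_index(drop=True)


def direction_binomial_test(n_co: int, n_anti: int) -> float:
    """One-tailed exact binomial P(X >= n_co | n_co + n_anti, 1/2)."""
    n = n_co + n_anti
    if n == 0:
        raise ValueError("no triples to test")
    return float(stats.binomtest(n_co, n, 0.5, alternative="greater").pvalue)


def filter_peaks(peaks: pd.DataFrame, min_log2fc: float = 3.0,
                 max_p: float = 0.001) -> pd.DataFrame:
    """Retain eCLIP peaks with log2 enrichment >= 3 and P < 0.001."""
    return peaks[(peaks["log2fc"] >= min_log2fc) & (peaks["p"] < max_p)]


def merge_intervals(intervals):
    """Union of half-open intervals; idempotent and order-independent."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(iv) for iv in merged]


def eclip_support(triples: pd.DataFrame, peaks: pd.DataFrame,
                  window: int = 20, min_log2fc: float = 3.0,
                  max_p: float = 0.001):
    """Flag triples backed by an eCLIP peak of the same RBP near the miSS.

    Peaks (columns ``chrom, start, end, rbp, log2fc, p``; replicates and
    cell lines stacked) are filtered, unioned per (rbp, chrom) by interval
    merge, and a triple is supported iff [pos - window, pos + window]
    around its miSS (columns ``chrom, pos`` in ``triples``) overlaps a
    same-RBP peak.  Enrichment of co-directed triples among the supported
    ones is tested by a one-tailed Fisher exact test.

    Returns
    -------
    (flags, fisher_p) : boolean Series aligned with ``triples`` and the
    one-tailed P-value (NaN when a margin of the 2x2 table is empty).
    """
    good = filter_peaks(peaks, min_log2fc, max_p)
    unions = {}
    for (rbp, chrom), sub in good.groupby(["rbp", "chrom"]):
        unions[(rbp, chrom)] = merge_intervals(
            zip(sub["start"], sub["end"]))
    flags = []
    for _, row in triples.iterrows():
        ivs = unions.get((row["rbp"], row["chrom"]), [])
        lo, hi = row["pos"] - window, row["pos"] + window
        flags.append(any(a <= hi and lo <= b for a, b in ivs))
    flags = pd.Series(flags, index=triples.index, name="eclip_supported")

    co = (triples["direction"] == "co").to_numpy()
    sup = flags.to_numpy()
    table = [[int((co & sup).sum()), int((~co & sup).sum())],
             [int((co & ~sup).sum()), int((~co & ~sup).sum())]]
    if min(sum(table[0]), sum(table[1])) == 0:
        fisher_p = float("nan")
    else:
        fisher_p = float(stats.fisher_exact(table,
                                            alternative="greater")[1])
    return flags, fisher_p


def compare_oe_kd(events: pd.DataFrame, proximal_cut: int = 5,
                  q_thresh: float = 0.05, dphi_thresh: float = 0.05):
    """Contrast miSS responses to RBP overexpression vs knockdown.

    ``events`` has columns ``miss_id, shift, dphi_oe, q_oe, dphi_kd, q_kd``.
    Events significant (q < q_thresh) and substantial (|dphi| > dphi_thresh)
    in either the overexpression or the knockdown arm are retained.  A
    direct regulator produces anticorrelated responses; proximal
    (|shift| < proximal_cut) and distal miSS may respond with opposite
    signs, which the per-group medians and a rank test expose.

    Returns a dict with ``events`` (the filtered table), ``pearson_r``,
    ``spearman_r``, per-group median responses and the two-sided
    Mann-Whitney P comparing proximal vs distal overexpression responses.
    """
    sel_oe = (events["q_oe"] < q_thresh) & (events["dphi_oe"].abs()
                                            > dphi_thresh)
    sel_kd = (events["q_kd"] < q_thresh) & (events["dphi_kd"].abs()
                                            > dphi_thresh)
    ev = events[sel_oe | sel_kd].copy()
    if len(ev) < 2:
        raise ValueError("fewer than two qualifying events")
    x, y = ev["dphi_oe"].to_numpy(), ev["dphi_kd"].to_numpy()
    pearson = float(stats.pearsonr(x, y)[0])
    spearman = float(stats.spearmanr(x, y)[0])
    prox = ev["shift"].abs() < proximal_cut
    out = {
        "events": ev,
        "pearson_r": pearson,
        "spearman_r": spearman,
        "median_oe_proximal": float(np.median(x[prox])) if prox.any()
        else float("nan"),
        "median_oe_distal": float(np.median(x[~prox])) if (~prox).any()
        else float("nan"),
        "median_kd_proximal": float(np.median(y[prox])) if prox.any()
        else float("nan"),
        "median_kd_distal": float(np.median(y[~prox])) if (~prox).any()
        else float("nan"),
    }
    if prox.any() and (~prox).any():
        out["mannwhitney_p"] = float(stats.mannwhitneyu(
            x[prox], x[~prox], alternative="two-sided").pvalue)
    else:
        out["mannwhitney_p"] = float("nan")
    return out
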