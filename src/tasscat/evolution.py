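"""Evolutionary selection on splice sites via the O/E substitution statistic.

Each nucleotide variant at each splice-site position is classed as
consensus (Cn) or non-consensus (Nc) from a position weight matrix built
on constitutive splice sites.  The ancestral state of the human/marmoset
common ancestor is reconstructed by parsimony with galago as the outgroup,
and substitutions accumulated on the marmoset lineage (independent of the
human lineage, avoiding ascertainment towards the human state) are counted
by class: an ancestral Cn base is an opportunity for a Cn-to-Nc
substitution, and symmetrically for Nc-to-Cn.  The expected count under
neutrality comes from per-base substitution rates in neutrally evolving
intronic background; O/E < 1 indicates purifying selection, O/E > 1
positive selection.  Confidence limits for O/E use the score statistic for
a ratio of two binomial proportions (Koopman-type), and the fraction alpha
of "noisy" sites in a category is estimated by matching its O/E against
resampled mixtures of cryptic (noisy) and constitutive (functional) sites.

Sequence window conventions
---------------------------
Donor sites are given as the 6 intronic nucleotides +1..+6 (GT at +1,+2;
analysis positions +3..+6).  Acceptor sites are the 24 intronic
nucleotides -24..-1 (AG at -2,-1; analysis positions -24..-3).  All
sequences are in transcript orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

__all__ = ["ConsensusMap", "BackgroundRates", "build_consensus_map",
           "parsimony_ancestor", "parsimony_ancestor_array",
           "background_rates", "site_substitution_stats",
           "SubstitutionTable", "aggregate_oe", "oe_ratio_ci",
           "match_by_strength", "AlphaEstimate", "estimate_alpha",
           "max_allele_frequency", "seq_to_ints", "ints_to_seq"]

_NTS = np.array(["A", "C", "G", "T"])
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

DONOR_WINDOW = 6
ACCEPTOR_WINDOW = 24
# indices of analysis positions / obligate dinucleotide within the window
_ANALYSIS_IDX = {"donor": np.arange(2, 6), "acceptor": np.arange(0, 22)}
_DINUC_IDX = {"donor": (0, 1), "acceptor": (22, 23)}
_DINUC = {"donor": "GT", "acceptor": "AG"}


def seq_to_ints(sequences) -> np.ndarray:
    """Stack equal-length ACGT strings into an (n, L) uint8 array.

    Integer arrays (0=A, 1=C, 2=G, 3=T) pass through unchanged, so the
    counting routines accept either representation.
    """
    if isinstance(sequences, np.ndarray) and sequences.dtype != object \
            and np.issubdtype(sequences.dtype, np.integer):
        return sequences.astype(np.uint8, copy=False)
    arr = np.array([list(s.upper()) for s in sequences])
    out = np.zeros(arr.shape, dtype=np.uint8)
    for nt, i in _NT_INDEX.items():
        out[arr == nt] = i
    bad = ~np.isin(arr, _NTS)
    if bad.any():
        raise ValueError("sequences contain non-ACGT characters")
    return out


def ints_to_seq(row) -> str:
    return "".join(_NTS[row])


@dataclass
class ConsensusMap:
    """Per-position Cn/Nc classification derived from a constitutive PWM.

    ``cn`` is an (L, 4) boolean array: cn[p, b] is True iff base b at
    window position p occurs in constitutive sites with frequency at least
    ``cn_threshold``.  Obligate GT/AG positions are excluded from the
    analysis range.
    """

    kind: str
    pwm: np.ndarray
    cn: np.ndarray
    cn_threshold: float

    @property
    def analysis_idx(self) -> np.ndarray:
        return _ANALYSIS_IDX[self.kind]

    @property
    def window(self) -> int:
        return self.pwm.shape[0]


def build_consensus_map(constitutive_sequences, kind: str,
                        cn_threshold: float = 0.35,
                        min_sequences: int = 100) -> ConsensusMap:
    """PWM and Cn/Nc classification from constitutive splice-site windows.

    Fewer than ``min_sequences`` inputs make the PWM (and hence the
    classification boundary) unstable and raise an error.
    """
    if kind not in _ANALYSIS_IDX:
        raise ValueError(f"unknown site kind {kind!r}")
    ints = seq_to_ints(constitutive_sequences)
    if ints.shape[0] < min_sequences:
        raise ValueError(f"need >= {min_sequences} constitutive sequences, "
                         f"got {ints.shape[0]}")
    expected = DONOR_WINDOW if kind == "donor" else ACCEPTOR_WINDOW
    if ints.shape[1] != expected:
        raise ValueError(f"{kind} windows must be {expected} nt")
    pwm = np.stack([(ints == b).mean(axis=0) for b in range(4)], axis=1)
    cn = pwm >= cn_threshold
    return ConsensusMap(kind, pwm, cn, cn_threshold)


def parsimony_ancestor(human: str, marmoset: str, galago: str):
    """Ancestral base of the human/marmoset ancestor, or None if ambiguous.

    Ingroup agreement wins; otherwise the outgroup resolves the tie when it
    matches exactly one ingroup base; a three-way conflict is ambiguous.
    """
    h, m, g = human.upper(), marmoset.upper(), galago.upper()
    if h == m:
        return h
    if g == h:
        return h
    if g == m:
        return m
    return None


def parsimony_ancestor_array(h: np.ndarray, m: np.ndarray,
                             g: np.ndarray) -> np.ndarray:
    """Vectorized parsimony over integer base arrays; -1 where ambiguous."""
    anc = np.full(h.shape, -1, dtype=np.int8)
    anc[h == m] = h[h == m]
    tie = h != m
    anc[tie & (g == h)] = h[tie & (g == h)]
    anc[tie & (g == m)] = m[tie & (g == m)]
    return anc


@dataclass
class BackgroundRates:
    """Substitution rates from neutrally evolving background alignments.

    Pooled form: ``counts[b]`` background positions with ancestral base b,
    ``subs[b, c]`` of which substituted to c on the analysed lineage, so
    ``rate(b, c) = subs[b, c] / counts[b]``.  Position-stratified form
    (``per_position=True``): counts is (L, 4) and subs (L, 4, 4), rates
    estimated separately at every window position.  Stratifying by
    position as well as by ancestral base keeps the expected counts
    consistent when ancestor misreconstruction (double hits resolved
    wrongly by the outgroup) inflates apparent rates in a
    composition-dependent way; a background whose positional composition
    matches the analysed sites then calibrates O/E to 1 under neutrality.
    """

    counts: np.ndarray
    subs: np.ndarray
    per_position: bool = False

    @property
    def rate_matrix(self) -> np.ndarray:
        """(4, 4) pooled or (L, 4, 4) per-position rate array."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.nan_to_num(self.subs / self.counts[..., None])

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())


def background_rates(human_seqs, marmoset_seqs, galago_seqs,
                     lineage: str = "marmoset",
                     per_position: bool = False) -> BackgroundRates:
    """Substitution rates from 3-taxon alignments of neutral DNA.

    With ``per_position=True`` the input windows must be column-aligned to
    the splice-site windows they calibrate (same width), and rates are
    estimated per window position.
    """
    H = seq_to_ints(human_seqs)
    M = seq_to_ints(marmoset_seqs)
    G = seq_to_ints(galago_seqs)
    anc = parsimony_ancestor_array(H, M, G)
    derived = M if lineage == "marmoset" else H
    ok = anc >= 0
    if per_position:
        L = H.shape[1]
        counts = np.zeros((L, 4))
        subs = np.zeros((L, 4, 4))
        pos = np.broadcast_to(np.arange(L), H.shape)
        a, d, p = anc[ok], derived[ok], pos[ok]
        np.add.at(counts, (p, a), 1.0)
        changed = d != a
        np.add.at(subs, (p[changed], a[changed], d[changed]), 1.0)
        if (counts.sum(axis=1) == 0).any():
            raise ValueError("a background column has no unambiguous sites")
    else:
        a, d = anc[ok].ravel(), derived[ok].ravel()
        counts = np.bincount(a, minlength=4).astype(float)
        subs = np.zeros((4, 4))
        changed = d != a
        np.add.at(subs, (a[changed], d[changed]), 1.0)
        if (counts == 0).any():
            raise ValueError("background lacks some ancestral base entirely")
    return BackgroundRates(counts, subs, per_position)


def site_substitution_stats(human_seqs, marmoset_seqs, galago_seqs,
                            cmap: ConsensusMap, bg: BackgroundRates,
                            lineage: str = "marmoset") -> pd.DataFrame:
    """Per-site observed and expected substitution counts by class.

    Only sites with the canonical GT/AG dinucleotide in all three genomes
    are counted (``canonical`` column; others carry NaN stats).  Within the
    analysis positions, each unambiguous ancestral base contributes one
    opportunity of its class; a substitution on the analysed lineage that
    lands in the opposite class contributes one observed event; and the
    expected count is the sum over opportunities of the background rates
    into the opposite class.

    Returns a DataFrame with columns ``canonical, obs_cn2nc, opp_cn,
    exp_cn2nc, obs_nc2cn, opp_nc, exp_nc2cn``.
    """
    H = seq_to_ints(human_seqs)
    M = seq_to_ints(marmoset_seqs)
    G = seq_to_ints(galago_seqs)
    if not (H.shape == M.shape == G.shape):
        raise ValueError("alignment blocks differ in shape")
    n = H.shape[0]
    di = _DINUC_IDX[cmap.kind]
    di_bases = np.array([_NT_INDEX[c] for c in _DINUC[cmap.kind]],
                        dtype=np.uint8)
    canonical = np.ones(n, dtype=bool)
    for arr in (H, M, G):
        canonical &= (arr[:, di[0]] == di_bases[0]) \
            & (arr[:, di[1]] == di_bases[1])

    idx = cmap.analysis_idx
    h, m, g = H[:, idx], M[:, idx], G[:, idx]
    anc = parsimony_ancestor_array(h, m, g)
    derived = m if lineage == "marmoset" else h
    valid = anc >= 0
    anc_safe = np.where(valid, anc, 0)

    # class of the ancestral and derived base at each analysed position
    cn_pos = cmap.cn[idx]                         # (P, 4)
    pos_grid = np.broadcast_to(np.arange(len(idx)), anc_safe.shape)
    anc_class_cn = cn_pos[pos_grid, anc_safe.astype(int)]
    anc_is_cn = anc_class_cn & valid
    anc_is_nc = ~anc_class_cn & valid
    der_is_cn = cn_pos[pos_grid, derived.astype(int)]
    substituted = (derived != anc_safe) & valid

    obs_cn2nc = (anc_is_cn & substituted & ~der_is_cn).sum(axis=1)
    obs_nc2cn = (anc_is_nc & substituted & der_is_cn).sum(axis=1)
    opp_cn = anc_is_cn.sum(axis=1)
    opp_nc = anc_is_nc.sum(axis=1)

    # expected events: sum over opportunities of background rates into the
    # opposite class (excluding the ancestral base itself)
    rates = bg.rate_matrix                  # (4, 4) or (L, 4, 4)
    to_nc = np.zeros((len(idx), 4))         # (P, base) -> rate to Nc
    to_cn = np.zeros((len(idx), 4))
    for p, gp in enumerate(idx):
        rmat = rates[gp] if bg.per_position else rates
        for b in range(4):
            others = [c for c in range(4) if c != b]
            to_nc[p, b] = sum(rmat[b, c] for c in others
                              if not cn_pos[p, c])
            to_cn[p, b] = sum(rmat[b, c] for c in others
                              if cn_pos[p, c])
    exp_cn2nc = np.where(anc_is_cn, to_nc[pos_grid, anc_safe.astype(int)],
                         0.0).sum(axis=1)
    exp_nc2cn = np.where(anc_is_nc, to_cn[pos_grid, anc_safe.astype(int)],
                         0.0).sum(axis=1)

    out = pd.DataFrame({
        "canonical": canonical,
        "obs_cn2nc": obs_cn2nc.astype(float),
        "opp_cn": opp_cn.astype(float),
        "exp_cn2nc": exp_cn2nc,
        "obs_nc2cn": obs_nc2cn.astype(float),
        "opp_nc": opp_nc.astype(float),
        "exp_nc2cn": exp_nc2cn,
    })
    stat_cols = out.columns[1:]
    out.loc[~canonical, stat_cols] = np.nan

    # aggregate opportunity counts by (analysis position, ancestral base),
    # needed downstream for the background-side effective sample size
    canon = canonical[:, None] & np.ones_like(valid)
    opp_mat_cn = np.zeros((len(idx), 4))
    opp_mat_nc = np.zeros((len(idx), 4))
    sel_cn = anc_is_cn & canon
    sel_nc = anc_is_nc & canon
    np.add.at(opp_mat_cn, (pos_grid[sel_cn], anc_safe[sel_cn].astype(int)),
              1.0)
    np.add.at(opp_mat_nc, (pos_grid[sel_nc], anc_safe[sel_nc].astype(int)),
              1.0)
    out.attrs["opp_matrix_cn"] = opp_mat_cn
    out.attrs["opp_matrix_nc"] = opp_mat_nc
    out.attrs["q_to_nc"] = to_nc
    out.attrs["q_to_cn"] = to_cn
    out.attrs["analysis_idx"] = idx
    return out


@dataclass
class SubstitutionTable:
    """Aggregate O/E for one substitution class in one site category."""

    category: str
    direction: str            # "cn2nc" or "nc2cn"
    obs: float
    opp: float
    expected: float
    bg_n: float
    oe: float
    ci_low: float
    ci_high: float


def aggregate_oe(stats_df: pd.DataFrame, bg: BackgroundRates,
                 direction: str = "cn2nc", category: str = "",
                 conf: float = 0.95) -> SubstitutionTable:
    """Category-level O/E with a score CI from per-site stats.

    O = sum of observed events, E = sum of per-site expected events; the
    CI treats the category as x1/n1 successes over opportunities against
    an effective background proportion E/n1 carried by the background
    sample size n2 (two-binomial score interval).
    """
    sub = stats_df[stats_df["canonical"].fillna(False)]
    obs = float(sub[f"obs_{direction}"].sum())
    opp = float(sub["opp_cn" if direction == "cn2nc" else "opp_nc"].sum())
    exp = float(sub[f"exp_{direction}"].sum())
    if opp == 0 or exp == 0:
        raise ValueError("no opportunities (or zero expectation) in category")
    p2 = exp / opp
    n2 = _effective_background_n(stats_df, bg, direction, p2)
    x2 = p2 * n2
    oe, lo, hi = oe_ratio_ci(obs, opp, x2, n2, conf=conf)
    return SubstitutionTable(category, direction, obs, opp, exp, n2, oe,
                             lo, hi)


def _effective_background_n(stats_df, bg: BackgroundRates, direction: str,
                            p2: float) -> float:
    """Binomial-equivalent sample size of the background-side estimate.

    The expected rate p2 is an opportunity-weighted combination of
    per-stratum background rates; its delta-method variance over the
    (position, ancestral base) strata converts to the n of a binomial
    proportion with the same variance, which the score CI consumes.
    Falls back to the raw background size when the stratum bookkeeping is
    unavailable (pooled background) — a mild understatement of the CI
    width in that legacy mode.
    """
    attrs = stats_df.attrs
    if not bg.per_position or "opp_matrix_cn" not in attrs:
        return bg.n_total
    opp_mat = attrs["opp_matrix_cn" if direction == "cn2nc"
                    else "opp_matrix_nc"]
    q = attrs["q_to_nc" if direction == "cn2nc" else "q_to_cn"]
    idx = attrs["analysis_idx"]
    total = opp_mat.sum()
    var = 0.0
    for p, gp in enumerate(idx):
        for b in range(4):
            w = opp_mat[p, b] / total
            if w == 0:
                continue
            n_pb = bg.counts[gp, b]
            if n_pb <= 0:
                continue
            var += w * w * q[p, b] * (1 - q[p, b]) / n_pb
    if var <= 0:
        return bg.n_total
    return float(p2 * (1 - p2) / var)


def _koopman_chi2(theta, x1, n1, x2, n2):
    # constrained MLE of p2 under p1 = theta * p2 (quadratic root)
    a = theta * (n1 + n2)
    b = -(theta * (n1 + x2) + x1 + n2)
    c = x1 + x2
    disc = max(b * b - 4 * a * c, 0.0)
    p2 = (-b - np.sqrt(disc)) / (2 * a)
    p1 = theta * p2
    eps = 1e-12
    p1 = min(max(p1, eps), 1 - eps)
    p2 = min(max(p2, eps), 1 - eps)
    t1 = (x1 - n1 * p1) ** 2 / (n1 * p1 * (1 - p1))
    t2 = (x2 - n2 * p2) ** 2 / (n2 * p2 * (1 - p2))
    return t1 + t2


def oe_ratio_ci(x1, n1, x2, n2, conf: float = 0.95):
    """Score confidence interval for the ratio of two binomial proportions.

    The interval inverts the score statistic for H0: p1/p2 = theta with the
    constrained maximum-likelihood estimate of (p1, p2) under H0
    (Koopman-type), solved numerically.  ``x2 = 0`` yields an infinite
    upper limit; ``x1 = 0`` a lower limit of zero.  Counts may be
    non-integer (effective counts), as the statistic is purely algebraic.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("opportunity totals must be positive")
    if x1 < 0 or x2 < 0 or x1 > n1 or x2 > n2:
        raise ValueError("counts outside [0, n]")
    crit = stats.chi2.ppf(conf, 1)

    def f(theta):
        return _koopman_chi2(theta, x1, n1, x2, n2) - crit

    if x1 == 0 and x2 == 0:
        raise ValueError("both substitution counts are zero")
    if x2 == 0:
        # infinite point estimate: only the lower limit is informative
        mid = 1.0
        while f(mid) > 0 and mid < 1e12:
            mid *= 4
        lo = _lower_root(f, mid) if f(mid) <= 0 else np.inf
        return np.inf, float(lo), np.inf

    oe = (x1 / n1) / (x2 / n2)
    lo = 0.0 if x1 == 0 else _lower_root(f, oe)
    hi = _upper_root(f, max(oe, 1e-9))
    return float(oe), float(lo), float(hi)


def _lower_root(f, theta_hat):
    lo = theta_hat / 2
    for _ in range(200):
        if f(lo) > 0:
            return brentq(f, lo, theta_hat, xtol=1e-10, rtol=1e-10)
        lo /= 2
        if lo < 1e-15:
            return 0.0
    return 0.0


def _upper_root(f, theta_hat):
    hi = theta_hat * 2
    for _ in range(200):
        if f(hi) > 0:
            return brentq(f, theta_hat, hi, xtol=1e-10, rtol=1e-10)
        hi *= 2
        if hi > 1e15:
            return np.inf
    return np.inf


def match_by_strength(target_strengths, pool_strengths, tol: float = 0.01,
                      rng=None):
    """Sample one control site per target, matched by strength within tol.

    Sampling is uniform without replacement from the pool; targets are
    visited in random order so that scarcity at one strength does not
    systematically starve later targets.  Returns an array of pool indices
    (-1 for unmatched targets).
    """
    rng = np.random.default_rng(rng)
    targets = np.asarray(target_strengths, dtype=float)
    pool = np.asarray(pool_strengths, dtype=float)
    used = np.zeros(pool.size, dtype=bool)
    matched = np.full(targets.size, -1, dtype=int)
    for i in rng.permutation(targets.size):
        cand = np.flatnonzero((np.abs(pool - targets[i]) <= tol) & ~used)
        if cand.size:
            j = int(rng.choice(cand))
            matched[i] = j
            used[j] = True
    return matched


@dataclass
class AlphaEstimate:
    """Extrapolated 95% interval for the noisy-site fraction alpha."""

    category: str
    alpha_low: float
    alpha_median: float
    alpha_high: float
    grid_step: float
    n_resamples: int
    eps_range: tuple


def _resample_oe(obs, exp, m, B, rng, with_replacement):
    """O/E components of B random subsets of size m from (obs, exp)."""
    n = obs.size
    if m == 0:
        return np.zeros(B), np.zeros(B)
    if with_replacement:
        idx = rng.integers(0, n, size=(B, m))
    else:
        keys = rng.random((B, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    return obs[idx].sum(axis=1), exp[idx].sum(axis=1)


def estimate_alpha(observed_oe: float, pos_obs, pos_exp, neg_obs, neg_exp,
                   k: int, grid_step: float = 0.0033, B: int = 300,
                   eps_range=(0.025, 0.5, 0.005), rng=None,
                   category: str = "",
                   max_window_fraction: float = 0.5) -> AlphaEstimate:
    """Bootstrap mixture-model interval for the noisy-site fraction.

    For every alpha on a [0, 1] grid, ``B`` samples of ``alpha*k`` sites
    from the negative (noisy, cryptic) set and ``(1-alpha)*k`` sites from
    the positive (functional, constitutive) set are drawn and their O/E
    (sum of observed over sum of expected events) recorded, giving the
    joint empirical distribution of (alpha, O/E).  For each margin eps in
    ``eps_range = (start, stop, step)``, the 2.5%/50%/97.5% quantiles of
    alpha conditional on |O/E - observed| < eps are computed, and each
    quantile is extrapolated to eps -> 0 by a least-squares line
    q(eps) = beta0 + beta1 * eps; the intercepts, clamped to [0, 1], form
    the interval.

    Two numerical guards stabilise the extrapolation when the O/E spread
    of the mixture is small relative to the stated eps grid: margins whose
    window captures more than ``max_window_fraction`` of all resampled
    points are no longer selective (their quantiles drift towards the
    unconditional alpha distribution) and are excluded from the fit; and
    because the quantile-vs-margin curves flatten as eps -> 0, the fitted
    intercepts are not allowed to narrow the interval below the quantiles
    observed at the smallest informative margin.

    Sampling is without replacement when the source set is large enough,
    otherwise with replacement (warned).
    """
    rng = np.random.default_rng(rng)
    pos_obs = np.asarray(pos_obs, dtype=float)
    pos_exp = np.asarray(pos_exp, dtype=float)
    neg_obs = np.asarray(neg_obs, dtype=float)
    neg_exp = np.asarray(neg_exp, dtype=float)

    alphas = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    alphas = np.clip(alphas, 0.0, 1.0)
    alpha_col, oe_col = [], []
    warned = False
    for alpha in alphas:
        m_neg = int(round(alpha * k))
        m_pos = k - m_neg
        wr_neg = m_neg > neg_obs.size
        wr_pos = m_pos > pos_obs.size
        if (wr_neg or wr_pos) and not warned:
            warnings.warn("source set smaller than subsample; sampling "
                          "with replacement", stacklevel=2)
            warned = True
        o_n, e_n = _resample_oe(neg_obs, neg_exp, m_neg, B, rng, wr_neg)
        o_p, e_p = _resample_oe(pos_obs, pos_exp, m_pos, B, rng, wr_pos)
        tot_e = e_n + e_p
        ok = tot_e > 0
        oe = np.full(B, np.nan)
        oe[ok] = (o_n + o_p)[ok] / tot_e[ok]
        alpha_col.append(np.full(B, alpha))
        oe_col.append(oe)
    alpha_all = np.concatenate(alpha_col)
    oe_all = np.concatenate(oe_col)
    good = ~np.isnan(oe_all)
    alpha_all, oe_all = alpha_all[good], oe_all[good]

    e0, e1, estep = eps_range
    eps_grid = np.arange(e0, e1 + estep / 2, estep)
    largest = np.abs(oe_all - observed_oe) < eps_grid[-1]
    if largest.sum() == 0:
        raise ValueError("no resampled O/E within the largest margin of "
                         "the observed value")
    rows = []
    for eps in eps_grid:
        sel = np.abs(oe_all - observed_oe) < eps
        if sel.sum() == 0 or sel.mean() > max_window_fraction:
            continue
        q = np.quantile(alpha_all[sel], [0.025, 0.5, 0.975])
        rows.append((eps, *q))
    if not rows:
        # every stated margin is either empty or non-selective; fall back
        # to the largest-margin conditional quantiles
        q = np.quantile(alpha_all[largest], [0.025, 0.5, 0.975])
        rows.append((eps_grid[-1], *q))
    arr = np.asarray(rows)
    intercepts = []
    for col in (1, 2, 3):
        if arr.shape[0] >= 2:
            slope, intercept = np.polyfit(arr[:, 0], arr[:, col], 1)
        else:
            intercept = arr[0, col]
        intercepts.append(float(np.clip(intercept, 0.0, 1.0)))
    # the flattening of q(eps) near zero makes a linear intercept overshoot;
    # never report an interval narrower than the smallest informative window
    intercepts[0] = min(intercepts[0], float(arr[0, 1]))
    intercepts[2] = max(intercepts[2], float(arr[0, 3]))
    lo, med, hi = np.sort(intercepts)
    return AlphaEstimate(category, lo, med, hi, grid_step, B,
                         tuple(eps_range))


_SNP_WINDOWS = {"donor": (-35, 6), "acceptor": (-21, 35)}


def max_allele_frequency(kind: str, strand: str, pos: int, variants):
    """Maximum SNP allele frequency in the kind-specific window of a site.

    The window is [-35, +6] nt for donors and [-21, +35] nt for acceptors
    in transcript orientation (negative offsets towards the exon for
    donors, towards the intron for acceptors, per the site's geometry).
    ``variants`` is an iterable of (genomic_pos, allele_frequency).
    Returns NaN when no SNP falls in the window.
    """
    lo, hi = _SNP_WINDOWS[kind]
    best = np.nan
    for g, af in variants:
        off = g - pos if strand == "+" else pos - g
        if lo <= off <= hi:
            best = af if np.isnan(best) else max(best, af)
    return float(best)
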