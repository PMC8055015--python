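"""Synthetic data generators for the TASS analysis chain.

Every generator mirrors the statistical structure the corresponding
analysis stage assumes, so the whole pipeline is exercisable without any
external download: split-read counts follow the zero-inflated Poisson law
conditional on maSS counts; tissue effects enter as slope deviations;
knockdown tables carry known co/anti regulatory structure; and 3-taxon
alignments evolve from PWM-drawn ancestors under a tunable selection
multiplier at splice-site analysis positions.

Determinism: each generator draws from its own RNG stream derived from
``(seed, stream_tag)``, so adding a call to one simulator never perturbs
the output of another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from tasscat import evolution
from tasscat.evolution import (ACCEPTOR_WINDOW, DONOR_WINDOW, _ANALYSIS_IDX,
                               _DINUC_IDX)

__all__ = ["SimConfig", "stream", "simulate_catalog", "simulate_zip_pairs",
           "simulate_counts", "simulate_kd", "donor_pwm_probs",
           "acceptor_pwm_probs", "draw_sites_from_pwm", "evolve",
           "simulate_alignments", "simulate_background_alignments",
           "simulate_mixture"]

# stream tags, one per generator
_STREAMS = {"catalog": 11, "counts": 12, "kd": 13, "alignments": 14,
            "mixture": 15, "background": 16}


@dataclass
class SimConfig:
    """Study conditions for all generators.

    The zero-inflated Poisson parameters are the per-tissue law of miSS
    counts conditional on maSS counts: lambda = a0 * r_maSS^a1 and
    pi = logit^-1(b0 + b1 * r_maSS).  maSS counts are log-normal
    (mu=4, sigma=1.5 on the log scale), spanning the orders of magnitude
    seen in pooled junction data.  The substitution process applies a
    per-branch per-base rate, scaled by ``selection_s`` for
    consensus-breaking changes at splice-site analysis positions.
    """

    seed: int = 0
    # catalogue
    n_clusters: int = 300
    coding_fraction: float = 0.7
    # counts
    tissues: tuple = ("brain", "liver", "lung", "heart", "muscle",
                      "testis", "skin", "kidney")
    samples_per_tissue: int = 10
    zip_a0: float = 0.05
    zip_a1: float = 0.9
    zip_b0: float = -1.0
    zip_b1: float = 0.0005
    log_mass_mu: float = 4.0
    log_mass_sigma: float = 1.5
    tissue_effect_frac: float = 0.2
    tissue_effect_size: float = 0.1
    # regulation
    n_rbps: int = 10
    co_fraction: float = 163 / 256
    # evolution
    branch_sub_rate: float = 0.06
    outgroup_rate_scale: float = 2.0
    selection_s: float = 1.0
    mixture_alpha: float = 0.5
    mixture_positive_s: float = 0.2


def stream(config_or_seed, name: str) -> np.random.Generator:
    """Independent RNG stream for one generator under a shared seed."""
    seed = (config_or_seed.seed if isinstance(config_or_seed, SimConfig)
            else int(config_or_seed))
    return np.random.default_rng(
        np.random.SeedSequence([seed, _STREAMS[name]]))


# ---------------------------------------------------------------------------
# catalogue

_SIZE_DIST = {2: 0.80, 3: 0.14, 4: 0.04, 5: 0.02}
_DONOR_SHIFTS = ([4, -4] * 4 + [2, -2] * 2 + [5, -5, 6, -6, 8, 1, -1, 3])
_ACCEPTOR_SHIFTS = ([3, -3] * 4 + [6, -6] * 2 + [9, 12, 4, -4, 2, -2, 1, 5])


def simulate_catalog(config: SimConfig):
    """Random TASS clusters with known structure.

    Returns a dict with ``sites`` (DataFrame: chrom, pos, strand, kind,
    cluster_id, true_rank, coding), ``coding_boundaries`` (set of
    (chrom, pos, strand) usable by the coding classifier) and ``clusters``
    (per-cluster truth: id, kind, strand, size, coding, shifts).
    Shift values concentrate at the motif-driven +-4 (donor) / +-3
    (acceptor) offsets.
    """
    rng = stream(config, "catalog")
    sizes = rng.choice(list(_SIZE_DIST), p=list(_SIZE_DIST.values()),
                       size=config.n_clusters)
    rows, cluster_rows, boundaries = [], [], set()
    for i, size in enumerate(sizes):
        kind = "donor" if rng.random() < 0.5 else "acceptor"
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = "chrS"
        anchor = 10_000 * (i + 1)
        shifts_pool = (_DONOR_SHIFTS if kind == "donor"
                       else _ACCEPTOR_SHIFTS)
        shifts = []
        while len(shifts) < size - 1:
            s = int(rng.choice(shifts_pool))
            if s not in shifts:
                shifts.append(s)
        coding = bool(rng.random() < config.coding_fraction)
        cid = f"cl{i}"
        positions = [anchor] + [
            anchor + (s if strand == "+" else -s) for s in shifts]
        for rank, pos in enumerate(positions, start=1):
            rows.append({"chrom": chrom, "pos": pos, "strand": strand,
                         "kind": kind, "cluster_id": cid,
                         "true_rank": rank, "coding": coding})
        if coding:
            boundaries.add((chrom, anchor, strand))
        cluster_rows.append({"cluster_id": cid, "kind": kind,
                             "strand": strand, "size": int(size),
                             "coding": coding, "shifts": tuple(shifts)})
    return {"sites": pd.DataFrame(rows),
            "clusters": pd.DataFrame(cluster_rows),
            "coding_boundaries": boundaries}


# ---------------------------------------------------------------------------
# counts

def simulate_zip_pairs(a0: float, a1: float, b0: float, b1: float, n: int,
                       rng, log_mass_mu: float = 4.0,
                       log_mass_sigma: float = 1.5):
    """(r_miss, r_mass) pairs drawn from the conditional ZIP law."""
    rng = np.random.default_rng(rng)
    r_mass = np.maximum(
        np.round(rng.lognormal(log_mass_mu, log_mass_sigma, n)), 1
    ).astype(int)
    lam = a0 * r_mass.astype(float) ** a1
    pi = expit(b0 + b1 * r_mass)
    zeros = rng.random(n) < pi
    r_miss = np.where(zeros, 0, rng.poisson(lam))
    return r_miss.astype(int), r_mass


def simulate_counts(config: SimConfig, n_miss: int = 200):
    """Per-sample junction counts for miSS/maSS pairs across tissues.

    For each of ``n_miss`` minor sites and each sample, r_maSS is drawn
    log-normal and r_miSS from the ZIP law with the tissue-modulated mean
    lambda = (a0 + a_t) * r_maSS^a1.  A fraction ``tissue_effect_frac``
    of miSS receives a deviation a_t = tissue_effect_size in one random
    tissue.

    Returns a dict with ``pairs`` (DataFrame: miss_id, tissue, sample_id,
    r_miss, r_mass), ``tissue_pairs`` (per-tissue aggregated counts) and
    ``effects`` (truth table: miss_id, tissue, a_t).
    """
    rng = stream(config, "counts")
    tissues = list(config.tissues)
    n_affected = int(round(config.tissue_effect_frac * n_miss))
    affected = rng.choice(n_miss, size=n_affected, replace=False)
    effect_tissue = rng.choice(len(tissues), size=n_affected)
    a_t = np.zeros((n_miss, len(tissues)))
    for i, t in zip(affected, effect_tissue):
        a_t[i, t] = config.tissue_effect_size

    rows = []
    for i in range(n_miss):
        for ti, tissue in enumerate(tissues):
            slope = config.zip_a0 + a_t[i, ti]
            n_s = config.samples_per_tissue
            r_mass = np.maximum(np.round(rng.lognormal(
                config.log_mass_mu, config.log_mass_sigma, n_s)), 1
            ).astype(int)
            lam = slope * r_mass.astype(float) ** config.zip_a1
            pi = expit(config.zip_b0 + config.zip_b1 * r_mass)
            zeros = rng.random(n_s) < pi
            r_miss = np.where(zeros, 0, rng.poisson(lam))
            for s in range(n_s):
                rows.append({"miss_id": f"m{i}", "tissue": tissue,
                             "sample_id": f"{tissue}_{s}",
                             "r_miss": int(r_miss[s]),
                             "r_mass": int(r_mass[s])})
    pairs = pd.DataFrame(rows)
    tissue_pairs = (pairs.groupby(["miss_id", "tissue"], as_index=False)
                    [["r_miss", "r_mass"]].sum())
    effects = pd.DataFrame(
        [{"miss_id": f"m{i}", "tissue": tissues[t],
          "a_t": config.tissue_effect_size}
         for i, t in zip(affected, effect_tissue)])
    return {"pairs": pairs, "tissue_pairs": tissue_pairs,
            "effects": effects}


# ---------------------------------------------------------------------------
# regulation

def simulate_kd(config: SimConfig, n_triples: int = 120,
                eclip_support_fraction: float = 0.5):
    """KD/DE/specificity tables with known co/anti regulatory structure.

    Each triple gets a truth direction label (co with probability
    ``co_fraction``); two delta signs are drawn at random and the third is
    solved from the sign-product rule, with magnitudes above the analysis
    thresholds.  Both cell lines receive concordant knockdown responses.
    eCLIP peaks are placed within +-20 nt of the miSS for supported
    triples and 25-60 nt away otherwise.

    Returns a dict with ``kd`` (miss_id, rbp, cell_line, dphi_kd, p, q),
    ``rbp_de``, ``specific_miss``, ``peaks`` and ``truth``.
    """
    rng = stream(config, "kd")
    tissues = list(config.tissues)
    rbps = [f"RBP{j}" for j in range(config.n_rbps)]
    kd_rows, de_rows, miss_rows, peak_rows, truth_rows = [], [], [], [], []
    seen_de, seen_kd = {}, set()
    for i in range(n_triples):
        miss = f"m{i}"
        rbp = rbps[int(rng.integers(len(rbps)))]
        tissue = tissues[int(rng.integers(len(tissues)))]
        pos = 5_000 * (i + 1)
        chrom = "chrS"
        is_co = rng.random() < config.co_fraction
        s_t = 1 if rng.random() < 0.5 else -1
        # the RBP-tissue fold change is shared between all triples of that
        # pair, so its sign is drawn once and reused
        if (rbp, tissue) not in seen_de:
            log2fc = (1 if rng.random() < 0.5 else -1) \
                * rng.uniform(0.6, 3.0)
            de_rows.append({"rbp": rbp, "tissue": tissue,
                            "log2fc": log2fc, "q": 0.001})
            seen_de[(rbp, tissue)] = log2fc
        s_r = 1 if seen_de[(rbp, tissue)] > 0 else -1
        target = -1 if is_co else 1
        s_kd = target * s_t * s_r
        dphi_t = s_t * rng.uniform(0.06, 0.3)
        dphi_kd = s_kd * rng.uniform(0.06, 0.4)
        miss_rows.append({"miss_id": miss, "tissue": tissue,
                          "dphi_t": dphi_t, "chrom": chrom, "pos": pos})
        if (miss, rbp) not in seen_kd:
            for cell_line in ("K562", "HepG2"):
                jitter = rng.normal(0, 0.01)
                kd_rows.append({"miss_id": miss, "rbp": rbp,
                                "cell_line": cell_line,
                                "dphi_kd": dphi_kd + jitter,
                                "p": 1e-4, "q": 0.001})
            seen_kd.add((miss, rbp))
        supported = rng.random() < eclip_support_fraction
        if supported:
            start = pos - int(rng.integers(0, 15))
            end = start + int(rng.integers(10, 30))
        elif rng.random() < 0.5:
            start, end = pos + 25, pos + 40   # strictly beyond +20 nt
        else:
            start, end = pos - 40, pos - 25
        peak_rows.append({"chrom": chrom, "start": start, "end": end,
                          "rbp": rbp, "log2fc": 4.0, "p": 1e-5})
        truth_rows.append({"miss_id": miss, "rbp": rbp, "tissue": tissue,
                           "direction": "co" if is_co else "anti",
                           "eclip_supported": supported})
    return {"kd": pd.DataFrame(kd_rows), "rbp_de": pd.DataFrame(de_rows),
            "specific_miss": pd.DataFrame(miss_rows),
            "peaks": pd.DataFrame(peak_rows),
            "truth": pd.DataFrame(truth_rows)}


# ---------------------------------------------------------------------------
# alignments / evolution

def donor_pwm_probs() -> np.ndarray:
    """Base probabilities for the donor window +1..+6 (GT obligate)."""
    probs = np.array([
        [0.00, 0.00, 1.00, 0.00],   # +1 G
        [0.00, 0.00, 0.00, 1.00],   # +2 T
        [0.60, 0.03, 0.34, 0.03],   # +3 A/G
        [0.68, 0.08, 0.12, 0.12],   # +4 A
        [0.07, 0.05, 0.82, 0.06],   # +5 G
        [0.16, 0.16, 0.20, 0.48],   # +6 T
    ])
    return probs / probs.sum(axis=1, keepdims=True)


def acceptor_pwm_probs() -> np.ndarray:
    """Base probabilities for the acceptor window -24..-1 (AG obligate)."""
    rows = []
    for offset in range(-24, 0):
        if offset == -2:
            rows.append([1.0, 0.0, 0.0, 0.0])      # A
        elif offset == -1:
            rows.append([0.0, 0.0, 1.0, 0.0])      # G
        elif offset == -3:
            rows.append([0.06, 0.65, 0.01, 0.28])  # C-rich
        elif offset >= -20:
            rows.append([0.09, 0.31, 0.10, 0.50])  # polypyrimidine tract
        else:
            rows.append([0.21, 0.27, 0.21, 0.31])  # tract shoulder
    probs = np.asarray(rows, dtype=float)
    return probs / probs.sum(axis=1, keepdims=True)


def draw_sites_from_pwm(probs: np.ndarray, n: int, rng) -> np.ndarray:
    """Ancestral site windows sampled column-wise from base probabilities."""
    rng = np.random.default_rng(rng)
    length = probs.shape[0]
    u = rng.random((n, length))
    cum = probs.cumsum(axis=1)
    return (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.uint8)


def evolve(seqs: np.ndarray, rate: float, rng, cn: np.ndarray | None = None,
           analysis_idx=None, s: float = 1.0, frozen_idx=()) -> np.ndarray:
    """One branch of evolution with per-base substitution probability.

    Each base mutates to each of the three alternatives with probability
    ``rate / 3``; at ``analysis_idx`` positions, changes from a consensus
    base into a non-consensus base are scaled by ``s`` (purifying
    selection for s < 1).  ``frozen_idx`` positions (obligate GT/AG) never
    mutate.
    """
    rng = np.random.default_rng(rng)
    out = seqs.copy()
    length = seqs.shape[1]
    analysis = set(np.atleast_1d(analysis_idx).tolist()) \
        if analysis_idx is not None else set()
    frozen = set(frozen_idx)
    for p in range(length):
        if p in frozen:
            continue
        for b in range(4):
            mask = seqs[:, p] == b
            m = int(mask.sum())
            if m == 0:
                continue
            targets = [c for c in range(4) if c != b]
            probs = np.full(3, rate / 3)
            if cn is not None and p in analysis and cn[p, b]:
                for j, c in enumerate(targets):
                    if not cn[p, c]:
                        probs[j] *= s
            cum = np.cumsum(probs)
            u = rng.random(m)
            choice = np.searchsorted(cum, u)  # 3 means "no substitution"
            new = out[mask, p]
            for j, c in enumerate(targets):
                new[choice == j] = c
            out[mask, p] = new
    return out


def simulate_alignments(config: SimConfig, n_sites: int, kind: str = "donor",
                        functional: bool = True,
                        cmap: evolution.ConsensusMap | None = None,
                        rng=None):
    """3-taxon aligned splice-site windows with a known selection regime.

    Ancestors are drawn from the kind's PWM; human and marmoset branches
    evolve independently at ``branch_sub_rate`` with consensus-breaking
    changes scaled by ``selection_s`` when ``functional``; galago evolves
    from the ancestor on a branch ``outgroup_rate_scale`` times longer.
    The obligate GT/AG dinucleotide is held fixed in all taxa.

    Returns a dict with uint8 arrays ``ancestor, human, marmoset, galago``.
    """
    rng = np.random.default_rng(rng) if rng is not None \
        else stream(config, "alignments")
    probs = donor_pwm_probs() if kind == "donor" else acceptor_pwm_probs()
    anc = draw_sites_from_pwm(probs, n_sites, rng)
    idx = _ANALYSIS_IDX[kind]
    frozen = _DINUC_IDX[kind]
    cn = cmap.cn if cmap is not None else None
    s = config.selection_s if functional else 1.0
    kwargs = dict(cn=cn, analysis_idx=idx, s=s, frozen_idx=frozen)
    human = evolve(anc, config.branch_sub_rate, rng, **kwargs)
    marmoset = evolve(anc, config.branch_sub_rate, rng, **kwargs)
    galago = evolve(anc, config.branch_sub_rate
                    * config.outgroup_rate_scale, rng, **kwargs)
    return {"ancestor": anc, "human": human, "marmoset": marmoset,
            "galago": galago}


def simulate_background_alignments(config: SimConfig, n_positions: int,
                                   rng=None, window: int = 50):
    """Neutral intronic 3-taxon alignments (uniform ancestral base use)."""
    rng = np.random.default_rng(rng) if rng is not None \
        else stream(config, "background")
    n = max(n_positions // window, 1)
    anc = rng.integers(0, 4, size=(n, window)).astype(np.uint8)
    human = evolve(anc, config.branch_sub_rate, rng)
    marmoset = evolve(anc, config.branch_sub_rate, rng)
    galago = evolve(anc, config.branch_sub_rate
                    * config.outgroup_rate_scale, rng)
    return {"ancestor": anc, "human": human, "marmoset": marmoset,
            "galago": galago}


def simulate_mixture(config: SimConfig, n_positive: int, n_negative: int,
                     k: int, kind: str = "donor",
                     cmap: evolution.ConsensusMap | None = None, rng=None):
    """Positive/negative site sets and a mixed sample with known alpha.

    The positive (functional) set evolves under selection
    ``mixture_positive_s``; the negative (noisy) set evolves neutrally
    from the same PWM.  The mixed sample of size ``k`` contains
    ``round(mixture_alpha * k)`` negative and the rest positive sites.

    Returns a dict with the two alignment sets and the index arrays
    ``mixed_pos_idx, mixed_neg_idx`` of the mixture members.
    """
    rng = np.random.default_rng(rng) if rng is not None \
        else stream(config, "mixture")
    pos_cfg = SimConfig(**{**config.__dict__,
                           "selection_s": config.mixture_positive_s})
    positive = simulate_alignments(pos_cfg, n_positive, kind=kind,
                                   functional=True, cmap=cmap, rng=rng)
    negative = simulate_alignments(config, n_negative, kind=kind,
                                   functional=False, cmap=cmap, rng=rng)
    m_neg = int(round(config.mixture_alpha * k))
    m_pos = k - m_neg
    if m_neg > n_negative or m_pos > n_positive:
        raise ValueError("mixture larger than its source sets")
    neg_idx = rng.choice(n_negative, size=m_neg, replace=False)
    pos_idx = rng.choice(n_positive, size=m_pos, replace=False)
    return {"positive": positive, "negative": negative,
            "mixed_pos_idx": pos_idx, "mixed_neg_idx": neg_idx,
            "alpha": config.mixture_alpha, "k": k}
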