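"""Splice-site catalogue construction and TASS cluster descriptive metrics.

A splice site is identified by ``(chrom, pos, strand, kind)`` where ``pos``
is the 0-based genomic coordinate of the exon/intron boundary on the intron
side and ``kind`` is ``"donor"`` or ``"acceptor"``.  Sites enter from three
sources — transcript annotation, split-read evidence ("expressed") and
sequence-only prediction ("cryptic") — and are merged into one catalogue.
Sites of the same kind on the same strand whose successive coordinates are
at most 30 nt apart form a TASS cluster; within a cluster the sites are
ranked by pooled read support, rank 1 being the major splice site (maSS)
and ranks >= 2 the minor splice sites (miSS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_KEY = ["chrom", "pos", "strand", "kind"]

__all__ = [
    "SpliceSite",
    "TassCluster",
    "NmdResponse",
    "merge_sources",
    "call_expressed",
    "filter_polymorphic_artifacts",
    "cluster",
    "rank_sites",
    "shift_and_frame",
    "classify_coding",
    "compute_phi",
    "nmd_response",
    "riboseq_support",
    "build_pwm",
    "pwm_strength",
]


@dataclass(frozen=True)
class SpliceSite:
    """A splice site with its evidence sources.

    ``sources`` is a subset of {"annotated", "expressed", "cryptic"};
    a cryptic flag is mutually exclusive with the other two.
    """

    chrom: str
    pos: int
    strand: str
    kind: str
    sources: frozenset = field(default_factory=frozenset)
    cryptic_score: float | None = None

    @property
    def key(self):
        return (self.chrom, self.pos, self.strand, self.kind)


@dataclass
class TassCluster:
    """A maximal chain of same-kind sites with successive gaps <= max_gap.

    Clusters violating the size filter or lacking an expressed member are
    kept with ``passes_filters=False`` rather than deleted, so that both
    pre- and post-filter catalogues can be reported.
    """

    id: str
    chrom: str
    strand: str
    kind: str
    members: list  # SpliceSite, ordered by genomic position
    passes_filters: bool = True
    coding: bool | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def positions(self):
        return [s.pos for s in self.members]


@dataclass(frozen=True)
class NmdResponse:
    """Response of a miSS to NMD inactivation, measured as phi_KD - phi_C."""

    miss_key: tuple
    phi_kd: float
    phi_control: float

    @property
    def delta(self) -> float:
        return self.phi_kd - self.phi_control


def merge_sources(annotated, expressed, cryptic, cryptic_scores=None):
    """Merge annotated, expressed and cryptic site lists into one catalogue.

    Parameters
    ----------
    annotated, expressed, cryptic : iterable of site keys
        Each element is ``(chrom, pos, strand, kind)``.
    cryptic_scores : mapping, optional
        Site key -> prediction score in [0, 1] for cryptic sites.

    Returns
    -------
    dict mapping site key -> SpliceSite

    The cryptic flag is dropped from any site that is also annotated or
    expressed: a site with expression or annotation evidence is by
    definition not cryptic.  Records whose kind conflicts with an existing
    record at the same (chrom, pos, strand) are rejected with a warning.
    """
    cryptic_scores = cryptic_scores or {}
    sources_by_key: dict[tuple, set] = {}
    kind_at_coord: dict[tuple, str] = {}
    rejected = []

    def _add(key, label):
        key = (str(key[0]), int(key[1]), str(key[2]), str(key[3]))
        coord = key[:3]
        if coord in kind_at_coord and kind_at_coord[coord] != key[3]:
            rejected.append(key)
            return
        kind_at_coord[coord] = key[3]
        sources_by_key.setdefault(key, set()).add(label)

    for key in annotated:
        _add(key, "annotated")
    for key in expressed:
        _add(key, "expressed")
    for key in cryptic:
        _add(key, "cryptic")

    if rejected:
        warnings.warn(
            f"rejected {len(rejected)} record(s) with conflicting donor/"
            f"acceptor kind at the same coordinate", stacklevel=2
        )

    catalogue = {}
    for key, src in sources_by_key.items():
        if src & {"annotated", "expressed"}:
            src.discard("cryptic")
        score = cryptic_scores.get(key) if "cryptic" in src else None
        catalogue[key] = SpliceSite(*key, sources=frozenset(src),
                                    cryptic_score=score)
    return catalogue


def call_expressed(junction_counts: pd.DataFrame, min_reads: int = 3,
                   min_tissues: int = 2, entropy_min: float = 1.5):
    """Call expressed sites from per-sample junction split-read counts.

    A site is expressed iff at least ``min_reads`` split reads support it in
    each of >= 2 samples coming from >= ``min_tissues`` distinct tissues.
    Junction records are filtered by offset-entropy >= ``entropy_min``
    (a guard against stacked mis-alignments); when the table carries no
    entropy column the filter is a pass-through with a warning.

    Parameters
    ----------
    junction_counts : DataFrame with columns
        ``site_id, sample_id, tissue, reads`` and optionally ``entropy``.

    Returns
    -------
    set of site_id
    """
    df = junction_counts
    if (df["reads"] < 0).any():
        raise ValueError("negative split-read counts")
    if "entropy" in df.columns:
        df = df[df["entropy"] >= entropy_min]
    else:
        warnings.warn("no entropy column; entropy filter is a pass-through",
                      stacklevel=2)
    qual = df[df["reads"] >= min_reads]
    grouped = qual.groupby("site_id").agg(
        n_samples=("sample_id", "nunique"), n_tissues=("tissue", "nunique"))
    ok = grouped[(grouped["n_samples"] >= 2)
                 & (grouped["n_tissues"] >= min_tissues)]
    return set(ok.index)


def filter_polymorphic_artifacts(sites, expressing_samples, variant_carriers):
    """Drop sites expressed only in samples carrying a nearby polymorphism.

    A germline variant inside the splice site or in the adjacent exon can
    cause split-read mis-alignment that mimics a novel site; such artifacts
    are expressed exclusively in the carrier samples.  A site is removed iff
    its set of expressing samples is non-empty and is a subset of its
    carrier set.

    Parameters
    ----------
    sites : iterable of site ids
    expressing_samples : mapping site id -> set of sample ids expressing it
    variant_carriers : mapping site id -> set of sample ids carrying a
        variant within the site or the adjacent exonic window

    Returns
    -------
    (kept, removed) : two lists of site ids
    """
    kept, removed = [], []
    for site in sites:
        expr = set(expressing_samples.get(site, ()))
        carriers = set(variant_carriers.get(site, ()))
        if expr and expr <= carriers:
            removed.append(site)
        else:
            kept.append(site)
    return kept, removed


def cluster(catalogue, max_gap: int = 30, max_size: int = 5):
    """Partition the catalogue into TASS clusters and standalone sites.

    Single-linkage chaining within (chrom, strand, kind): successive sites
    at most ``max_gap`` nt apart join the same cluster, so clusters are
    maximal by construction.  Clusters larger than ``max_size`` or without
    any expressed member are flagged (``passes_filters=False``) but kept.

    Returns
    -------
    (clusters, standalone) : list of TassCluster, list of SpliceSite
    """
    sites = sorted(catalogue.values(), key=lambda s: (s.chrom, s.strand,
                                                      s.kind, s.pos))
    clusters, standalone = [], []
    run: list[SpliceSite] = []

    def _flush(run):
        if len(run) >= 2:
            first = run[0]
            cid = f"{first.chrom}:{first.pos}:{first.strand}:{first.kind}"
            ok = (len(run) <= max_size
                  and any("expressed" in s.sources for s in run))
            clusters.append(TassCluster(cid, first.chrom, first.strand,
                                        first.kind, list(run),
                                        passes_filters=ok))
        elif run:
            standalone.append(run[0])

    for site in sites:
        if run and (site.chrom, site.strand, site.kind) == (
                run[-1].chrom, run[-1].strand, run[-1].kind) \
                and site.pos - run[-1].pos <= max_gap:
            run.append(site)
        else:
            _flush(run)
            run = [site]
    _flush(run)
    return clusters, standalone


def rank_sites(clust: TassCluster, pooled_counts):
    """Rank cluster members by pooled read support; rank 1 is the maSS.

    ``pooled_counts`` maps site key -> total split reads over all samples.
    Ties are broken in favour of the transcript-upstream site (5'-most in
    transcript orientation), which on the minus strand is the site with the
    larger genomic coordinate.  A cluster with zero total support has no
    maSS and is excluded (returns None).
    """
    counts = {s.key: int(pooled_counts.get(s.key, 0)) for s in clust.members}
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative pooled counts")
    if sum(counts.values()) == 0:
        return None
    upstream_sign = 1 if clust.strand == "+" else -1
    order = sorted(clust.members,
                   key=lambda s: (-counts[s.key], upstream_sign * s.pos))
    return {site.key: rank for rank, site in enumerate(order, start=1)}


def shift_and_frame(pos_miss: int, pos_mass: int, kind: str, strand: str):
    """Shift, frame class and exonic/intronic side of a miSS.

    The shift is the signed distance from maSS to miSS in transcript
    orientation (positive = miSS downstream in the gene), i.e. the genomic
    difference negated on the minus strand.  A shift that is a multiple of
    3 preserves the reading frame.  A donor miSS downstream of its maSS
    lies in the intron (the exon ends at the donor site), as does an
    acceptor miSS upstream of its maSS; otherwise the miSS is exonic.

    Returns
    -------
    (shift, frame_preserving, side)
    """
    genomic = pos_miss - pos_mass
    if genomic == 0:
        raise ValueError("miSS and maSS coincide")
    shift = genomic if strand == "+" else -genomic
    frame_preserving = shift % 3 == 0
    if kind == "donor":
        side = "intronic" if shift > 0 else "exonic"
    elif kind == "acceptor":
        side = "intronic" if shift < 0 else "exonic"
    else:
        raise ValueError(f"unknown site kind {kind!r}")
    return shift, frame_preserving, side


def classify_coding(clust: TassCluster, coding_boundaries) -> bool:
    """A cluster is coding iff it contains a non-terminal coding-exon boundary.

    ``coding_boundaries`` is a set of (chrom, pos, strand) internal CDS exon
    boundaries.  Non-coding clusters sit in UTRs or non-coding genes.
    """
    return any((s.chrom, s.pos, s.strand) in coding_boundaries
               for s in clust.members)


def compute_phi(r_miss, r_mass):
    """Relative miSS usage phi = r_miSS / (r_miSS + r_maSS).

    Counts only one end of each supporting split read; undefined (NaN) when
    both counts are zero.  Accepts scalars or arrays.
    """
    r_miss = np.asarray(r_miss, dtype=float)
    r_mass = np.asarray(r_mass, dtype=float)
    if (r_miss < 0).any() or (r_mass < 0).any():
        raise ValueError("negative read counts")
    denom = r_miss + r_mass
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, r_miss / np.where(denom > 0, denom, 1),
                       np.nan)
    return float(phi) if phi.ndim == 0 else phi


def nmd_response(miss_key, phi_kd: float, phi_control: float,
                 r_mass_control: int, min_mass_reads: int = 10):
    """phi_KD - phi_C response to NMD inactivation, or None if underpowered.

    TASS whose maSS has fewer than ``min_mass_reads`` control reads are
    discarded (phi is too unstable to interpret).
    """
    if r_mass_control < min_mass_reads:
        return None
    return NmdResponse(miss_key, float(phi_kd), float(phi_control))


def riboseq_support(reads_miss: float, reads_mass: float) -> float:
    """Relative Ribo-Seq support RS = reads_miSS / (reads_miSS + reads_maSS).

    Computed from footprint reads at the first exonic nucleotide of each
    site; intended for intronic miSS in clusters of size 2, where the two
    first exonic nucleotides are distinct.  NaN when both are zero.
    """
    if reads_miss < 0 or reads_mass < 0:
        raise ValueError("negative Ribo-Seq read counts")
    total = reads_miss + reads_mass
    return float(reads_miss) / total if total > 0 else float("nan")


_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def build_pwm(sequences) -> np.ndarray:
    """Position weight matrix (L x 4, columns A,C,G,T) from sequences."""
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences of unequal length")
    counts = np.zeros((length, 4))
    for s in seqs:
        for i, nt in enumerate(s):
            counts[i, _NT_INDEX[nt]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def pwm_strength(sequence: str, pwm: np.ndarray) -> float:
    """Log-odds splice-site strength against a uniform background.

    Score = sum over positions of log2(f_pos(nt) / 0.25), where f is the
    PWM built from constitutive splice sites.  Higher scores mean closer
    to the consensus; a uniform PWM scores 0 for every sequence.
    """
    sequence = sequence.upper()
    if len(sequence) != pwm.shape[0]:
        raise ValueError("sequence length does not match PWM")
    freqs = np.array([pwm[i, _NT_INDEX[nt]] for i, nt in enumerate(sequence)])
    if (freqs == 0).any():
        return -np.inf
    return float(np.log2(freqs / 0.25).sum())
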