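"""Plain-text readers and writers for the catalogue's external formats.

All coordinates are 0-based half-open (BED convention); a splice site is
identified by the genomic coordinate of the exon/intron boundary on the
intron side.
"""

from __future__ import annotations

import re

import pandas as pd

__all__ = ["read_junction_tsv", "write_catalog_tsv", "read_bed6",
           "write_bed6", "read_gtf_exons", "read_aligned_sites_tsv"]

JUNCTION_COLUMNS = ["site_id", "sample_id", "tissue", "reads", "entropy"]


def read_junction_tsv(path) -> pd.DataFrame:
    """Junction split-read counts: site_id, sample_id, tissue, reads[, entropy]."""
    df = pd.read_csv(path, sep="\t")
    missing = set(JUNCTION_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"junction table lacks columns: {sorted(missing)}")
    return df


def write_catalog_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bed6(path) -> pd.DataFrame:
    """BED6; the score column (x1000) carries cryptic prediction scores."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score",
                            "strand"], usecols=range(6))
    df["score"] = df["score"] / 1000.0
    return df


def write_bed6(df: pd.DataFrame, path, score_scale: float = 1000.0) -> None:
    out = df[["chrom", "start", "end", "name"]].copy()
    out["score"] = (df.get("score", 0) * score_scale).round().astype(int)
    out["strand"] = df["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_exons(path) -> pd.DataFrame:
    """Exon records from a GENCODE-style GTF (chrom, start, end, strand,
    gene_id, transcript_id, feature), with start converted to 0-based."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in ("exon", "CDS"):
                continue
            attrs = dict(_GTF_ATTR.findall(parts[8]))
            rows.append({"chrom": parts[0], "feature": parts[2],
                         "start": int(parts[3]) - 1, "end": int(parts[4]),
                         "strand": parts[6],
                         "gene_id": attrs.get("gene_id", ""),
                         "transcript_id": attrs.get("transcript_id", "")})
    return pd.DataFrame(rows)


def read_aligned_sites_tsv(path) -> pd.DataFrame:
    """3-taxon aligned splice-site windows:
    site_id, kind, strand, human_seq, marmoset_seq, galago_seq."""
    df = pd.read_csv(path, sep="\t")
    required = {"site_id", "kind", "human_seq", "marmoset_seq",
                "galago_seq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"aligned-sites table lacks: {sorted(missing)}")
    return df
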