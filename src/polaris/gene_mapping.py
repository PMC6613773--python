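"""Gene-model filtering and SNP-to-gene assignment with extended windows.

Gene models are restricted to KNOWN, protein-coding genes.  Each gene body
is extended into a window — by default 35 kb upstream and 10 kb downstream,
oriented by strand (so a minus-strand gene's 35 kb extension points toward
higher coordinates) — and every QC-passed SNP whose position falls inside
a window (1-based, both ends inclusive) is assigned to that gene.  SNPs in
overlapping windows are assigned to every gene they fall in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneModelSet, VariantRecord

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM = 35_000
DEFAULT_DOWNSTREAM = 10_000


@dataclass
class SnpGeneMap:
    """Variant-to-gene assignment: ``pairs`` (variant_id, gene_id) and the
    per-gene SNP counts (genes with zero SNPs are absent)."""

    pairs: pd.DataFrame
    counts: pd.Series

    def __post_init__(self) -> None:
        if self.pairs.duplicated(["variant_id", "gene_id"]).any():
            raise ValueError("duplicate (variant, gene) pairs in SNP-gene map")
        if len(self.pairs) != int(self.counts.sum()):
            raise ValueError("per-gene counts do not sum to the number of pairs")

    def snps_for(self, gene_id: str) -> list[str]:
        return self.pairs.loc[self.pairs["gene_id"] == gene_id, "variant_id"].tolist()

    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def __len__(self) -> int:
        return len(self.pairs)


def filter_gene_models(genes: GeneModelSet) -> GeneModelSet:
    """Keep KNOWN, protein-coding genes (case-insensitive field matching)."""
    t = genes.table
    keep = (t["status"].str.upper() == "KNOWN") & (t["biotype"].str.lower() == "protein_coding")
    kept = GeneModelSet(t[keep].reset_index(drop=True))
    if len(kept) == 0:
        logger.warning("gene-model filter kept no genes")
    logger.info("gene-model filter: %d of %d genes kept", len(kept), len(t))
    return kept


def build_windows(
    genes: GeneModelSet,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Extend gene bodies into score windows (1-based closed, clamped at 1).

    Strand-aware (default): a + strand gene becomes
    [start - upstream, end + downstream]; a - strand gene
    [start - downstream, end + upstream].  With ``strand_aware=False`` the
    + strand arithmetic applies regardless of strand.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window extensions must be non-negative")
    t = genes.table
    if strand_aware:
        minus = (t["strand"] == "-").to_numpy()
    else:
        minus = np.zeros(len(t), dtype=bool)
    left = np.where(minus, downstream, upstream)
    right = np.where(minus, upstream, downstream)
    out = pd.DataFrame({
        "gene_id": t["gene_id"],
        "gene_name": t["gene_name"],
        "chrom": t["chrom"],
        "strand": t["strand"],
        "gene_start": t["start"],
        "gene_end": t["end"],
        "window_start": np.maximum(1, t["start"].to_numpy() - left),
        "window_end": t["end"].to_numpy() + right,
    })
    return out


def assign_snps(variants: list[VariantRecord], windows: pd.DataFrame) -> SnpGeneMap:
    """Assign SNPs to every window containing them (inclusive boundaries).

    Genes whose windows contain no SNP are dropped from the map (and
    logged).  A disjoint chromosome vocabulary between the two inputs
    (e.g. 'chr1' vs '1') raises with a normalization hint.
    """
    var_chroms = {v.chrom for v in variants}
    win_chroms = set(windows["chrom"])
    if variants and len(windows) and not (var_chroms & win_chroms):
        stripped_v = {c.removeprefix("chr") for c in var_chroms}
        stripped_w = {c.removeprefix("chr") for c in win_chroms}
        hint = " (one side uses a 'chr' prefix — normalize chromosome names)" \
            if stripped_v & stripped_w else ""
        raise ValueError(
            f"no chromosome in common between variants ({sorted(var_chroms)}) and "
            f"gene windows ({sorted(win_chroms)}){hint}"
        )
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in var_chroms:
        vs = [(v.pos, v.id) for v in variants if v.chrom == chrom]
        vs.sort()
        by_chrom[chrom] = (np.array([p for p, _ in vs], dtype=np.int64), [i for _, i in vs])
    rows = []
    ordered = windows.sort_values(["chrom", "gene_start"], kind="stable")
    for w in ordered.itertuples():
        if w.chrom not in by_chrom:
            continue
        pos, ids = by_chrom[w.chrom]
        lo = np.searchsorted(pos, w.window_start, side="left")
        hi = np.searchsorted(pos, w.window_end, side="right")
        for k in range(lo, hi):
            rows.append((ids[k], w.gene_id))
    pairs = pd.DataFrame(rows, columns=["variant_id", "gene_id"])
    counts = pairs.groupby("gene_id", sort=False).size()
    n_empty = len(windows) - counts.size
    if n_empty:
        logger.info("%d gene window(s) contain no SNP and are dropped from the map", n_empty)
    return SnpGeneMap(pairs, counts)


def write_snp_gene_map(snp_map: SnpGeneMap, pairs_path, counts_path=None) -> None:
    from pathlib import Path

    pairs_path = Path(pairs_path)
    pairs_path.parent.mkdir(parents=True, exist_ok=True)
    snp_map.pairs.to_csv(pairs_path, sep="\t", index=False)
    if counts_path is not None:
        snp_map.counts.rename("n_snps").to_csv(counts_path, sep="\t")
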