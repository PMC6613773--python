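"""The POLARIS score: per-individual, per-gene LD-adjusted polygenic risk.

A classical polygenic risk score sums externally weighted allele counts,
which double-counts signal carried by correlated SNPs.  POLARIS corrects
for linkage disequilibrium through the spectral decomposition of the
within-gene SNP correlation matrix R = Q diag(lambda) Q', estimated from
the target cohort's own genotypes.  The marginal effect sizes beta from
the external study are transformed toward joint effects by the
ridge-regularized LD inverse

    w = Q (Lambda + k I)^{-1} Q' beta,

and each individual's gene score is the centered-genotype dot product
sum_j (g_ij - mean_j) w_j.  With k = 0 and full-rank R this is exactly
R^{-1} beta (the joint-effect solution); with R = I it reduces to the
classical centered PRS scaled by 1/(1 + k).  The ridge constant k
(default 1) keeps w finite when genes contain perfectly collinear SNPs,
which dense imputed data routinely produces; eigenvalues are never
truncated — regularization acts only through k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_mapping import SnpGeneMap
from .harmonize import HarmonizedWeights
from .io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

EIGENVALUE_TOL = 1e-8


@dataclass
class LDMatrix:
    """Within-gene SNP correlation matrix with its eigendecomposition
    (eigenvalues descending, eigenvectors as orthonormal columns)."""

    gene_id: str
    snp_ids: list[str]
    R: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray

    @property
    def m(self) -> int:
        return len(self.snp_ids)


@dataclass
class PolarisGeneScore:
    gene_id: str
    scores: np.ndarray  # one per sample
    m: int
    k: float

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("a gene score needs at least one SNP")
        if not np.isfinite(self.scores).all():
            raise ValueError(f"non-finite scores for gene {self.gene_id}")


@dataclass
class GeneScoreMatrix:
    """samples x genes score matrix plus per-gene metadata
    (gene_name, chrom, start, n_snps)."""

    scores: pd.DataFrame  # index = sample ids, columns = gene ids
    gene_info: pd.DataFrame  # index = gene ids
    k: float

    def gene_ids(self) -> list[str]:
        return list(self.scores.columns)

    def __len__(self) -> int:
        return self.scores.shape[1]


def _imputed_columns(gm: GenotypeMatrix, snp_ids: list[str]) -> np.ndarray:
    """Genotype columns for the named SNPs with missing entries replaced by
    the per-SNP mean of observed calls."""
    index = {v.id: j for j, v in enumerate(gm.variants)}
    try:
        cols = [index[s] for s in snp_ids]
    except KeyError as exc:
        raise KeyError(f"SNP {exc.args[0]} not present in genotype matrix") from exc
    g = gm.calls[:, cols].astype(np.float64)
    miss = gm.calls[:, cols] == MISSING
    if miss.any():
        observed = np.where(miss, np.nan, g)
        means = np.nanmean(observed, axis=0)
        idx = np.where(miss)
        g[idx] = np.take(means, idx[1])
    return g


def ld_correlation(gm: GenotypeMatrix, snp_ids: list[str], gene_id: str = "") -> LDMatrix:
    """Pearson correlation of (mean-imputed) genotype columns with its
    spectral decomposition attached.

    Eigenvalues within the numerical tolerance below zero are clipped to 0;
    anything more negative indicates a broken correlation matrix and raises.
    """
    if not snp_ids:
        raise ValueError("ld_correlation needs at least one SNP")
    g = _imputed_columns(gm, snp_ids)
    sd = g.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            "zero-variance genotype column(s) after imputation: "
            + ", ".join(snp_ids[j] for j in dead)
            + " (monomorphic SNPs should have been removed by the MAF filter)"
        )
    gc = (g - g.mean(axis=0)) / sd
    R = gc.T @ gc / g.shape[0]
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    eigvals, eigvecs = np.linalg.eigh(R)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    if eigvals[-1] < -EIGENVALUE_TOL:
        raise ValueError(f"gene {gene_id or '?'}: correlation matrix is not PSD")
    eigvals = np.clip(eigvals, 0.0, None)
    return LDMatrix(gene_id, list(snp_ids), R, eigvals, eigvecs)


def polaris_weights(ld: LDMatrix, betas: np.ndarray, k: float) -> np.ndarray:
    """Transform marginal effect sizes to LD-adjusted weights,
    w = Q (Lambda + kI)^{-1} Q' beta."""
    betas = np.asarray(betas, dtype=np.float64)
    if betas.shape != (ld.m,):
        raise ValueError(f"{betas.shape[0]} betas for {ld.m} SNPs")
    if k < 0:
        raise ValueError("ridge constant k must be non-negative")
    if k == 0.0 and ld.eigvals.min() < EIGENVALUE_TOL:
        raise ValueError(
            f"gene {ld.gene_id or '?'}: rank-deficient LD matrix "
            f"(min eigenvalue {ld.eigvals.min():.3g}); use a positive ridge constant k"
        )
    return ld.eigvecs @ ((ld.eigvecs.T @ betas) / (ld.eigvals + k))


def polaris_score(
    gm: GenotypeMatrix, snp_ids: list[str], w: np.ndarray, gene_id: str = "", k: float = np.nan
) -> PolarisGeneScore:
    """Per-sample gene score: centered (mean-imputed) genotypes dotted with
    the adjusted weights.  Centering makes the score location-free, and a
    missing genotype contributes exactly 0."""
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (len(snp_ids),):
        raise ValueError(f"{w.shape[0]} weights for {len(snp_ids)} SNPs")
    g = _imputed_columns(gm, snp_ids)
    gc = g - g.mean(axis=0)
    return PolarisGeneScore(gene_id, gc @ w, len(snp_ids), k)


def score_all_genes(
    gm: GenotypeMatrix,
    snp_map: SnpGeneMap,
    weights: HarmonizedWeights,
    k: float = 1.0,
    min_snps: int = 1,
    gene_info: pd.DataFrame | None = None,
) -> GeneScoreMatrix:
    """Score every mapped gene that has at least ``min_snps`` SNPs with
    harmonized weights present in the genotype matrix.

    Genes whose SNPs all lack weights (or genotypes) are dropped with a log
    entry.  ``gene_info`` (indexed or keyed by gene_id with gene_name,
    chrom, start columns — e.g. the window table) supplies the genomic
    metadata carried into association results.
    """
    beta_by_id = dict(zip(weights.table["id"], weights.table["beta_aligned"]))
    present = set(gm.variant_ids())
    columns: dict[str, np.ndarray] = {}
    info_rows = []
    meta = None
    if gene_info is not None:
        meta = gene_info.set_index("gene_id") if "gene_id" in gene_info.columns else gene_info
    for gene_id in snp_map.gene_ids():
        snps = [s for s in snp_map.snps_for(gene_id) if s in beta_by_id and s in present]
        if len(snps) < min_snps:
            logger.info("gene %s dropped: %d usable weighted SNP(s) (< %d)",
                        gene_id, len(snps), min_snps)
            continue
        ld = ld_correlation(gm, snps, gene_id)
        betas = np.array([beta_by_id[s] for s in snps])
        w = polaris_weights(ld, betas, k)
        columns[gene_id] = polaris_score(gm, snps, w, gene_id, k).scores
        row = {"gene_id": gene_id, "n_snps": len(snps)}
        if meta is not None and gene_id in meta.index:
            for col in ("gene_name", "chrom", "gene_start", "start"):
                if col in meta.columns:
                    row["start" if col == "gene_start" else col] = meta.loc[gene_id, col]
        info_rows.append(row)
    scores = pd.DataFrame(columns, index=list(gm.samples))
    info = pd.DataFrame(info_rows).set_index("gene_id") if info_rows else pd.DataFrame()
    return GeneScoreMatrix(scores, info, k)


def write_scores(gsm: GeneScoreMatrix, path) -> None:
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gsm.scores.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.10g")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
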