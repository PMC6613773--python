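"""Per-gene logistic-regression association scans on POLARIS scores.

Each gene's score is tested for association with case-control status in a
logistic model with covariates (age, sex, leading principal components by
default), reporting the Wald beta/SE/p for the score term.  Gene-wide
significance uses the conventional ~20,000-gene Bonferroni threshold
p < 2.5e-6.  A conditional scan re-tests genes with one or more other
genes' scores added to the model, to ask whether a signal is independent
of a dominant locus — the classic use being conditioning the region around
a major risk gene on that gene's own score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .io_formats import CovariateTable
from .polaris_core import GeneScoreMatrix

logger = logging.getLogger(__name__)

GENE_WIDE_ALPHA = 2.5e-6
DEFAULT_COVARIATES = ("age", "sex", "PC1", "PC2", "PC3")


class CollinearColumnsError(ValueError):
    """Design matrix is rank deficient."""


@dataclass(frozen=True)
class ScanConfig:
    alpha_gene: float = GENE_WIDE_ALPHA
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    condition_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_gene < 1.0):
            raise ValueError(f"alpha_gene must be in (0, 1), got {self.alpha_gene}")


@dataclass
class GeneAssociationResult:
    gene_id: str
    chrom: str
    n_snps: int
    beta: float
    se: float
    p: float
    significant: bool
    converged: bool
    conditioned_on: tuple[str, ...] = ()
    gene_name: str = ""
    start: int = 0


@dataclass
class LogisticFit:
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    names: list[str]
    converged: bool


def fit_logistic(y: np.ndarray, X: np.ndarray, names: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton/IRLS, tol 1e-8,
    max 100 iterations) with an intercept added internally.

    Raises on a single-class outcome or a rank-deficient design (naming the
    collinear columns).  Perfect separation yields a flagged non-converged
    fit with NaN standard errors and p-values — numbers are never invented.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} design rows for {y.shape[0]} outcomes")
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    if len(classes) < 2:
        raise ValueError("outcome has a single class; logistic model is undefined")
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    design = np.column_stack([np.ones(len(y)), X])
    all_names = ["intercept"] + names
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns via QR pivoting
        from scipy.linalg import qr

        _, _r, piv = qr(design, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        raise CollinearColumnsError(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(all_names[j] for j in bad)
        )
    import warnings

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        converged = bool(res.mle_retvals.get("converged", True))
        params, bse, pvalues = res.params, res.bse, res.pvalues
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        converged = False
        params = np.full(design.shape[1], np.nan)
        bse = np.full(design.shape[1], np.nan)
        pvalues = np.full(design.shape[1], np.nan)
    if converged and (not np.isfinite(bse).all() or np.abs(params).max() > 50):
        converged = False
        pvalues = np.full(design.shape[1], np.nan)
    return LogisticFit(np.asarray(params), np.asarray(bse), np.asarray(pvalues),
                       all_names, converged)


def _aligned_design(
    scores: GeneScoreMatrix, cov: CovariateTable, covariate_names: tuple[str, ...]
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Align score rows with covariate rows by sample id; drop samples with
    missing covariates (logged)."""
    covt = cov.table.set_index("sample_id")
    score_samples = set(scores.scores.index)
    cov_samples = set(covt.index)
    if score_samples != cov_samples:
        raise ValueError(
            f"sample mismatch between scores ({len(score_samples)}) and covariates "
            f"({len(cov_samples)}): {len(score_samples & cov_samples)} in common"
        )
    missing = [c for c in covariate_names if c not in covt.columns]
    if missing:
        raise ValueError(f"covariate(s) not in table: {', '.join(missing)}")
    covt = covt.loc[scores.scores.index]
    ok = covt[list(covariate_names)].notna().all(axis=1)
    if (~ok).any():
        logger.info("dropping %d sample(s) with missing covariates", int((~ok).sum()))
    covt = covt[ok]
    y = covt["phenotype"].to_numpy(float)
    return scores.scores.loc[covt.index], y, covt


def _result_from_fit(
    fit: LogisticFit, gene_id: str, info: pd.DataFrame, cfg: ScanConfig,
    conditioned_on: tuple[str, ...],
) -> GeneAssociationResult:
    meta = info.loc[gene_id] if gene_id in info.index else pd.Series(dtype=object)
    beta, se, p = (
        (fit.params[1], fit.bse[1], fit.pvalues[1]) if fit.converged
        else (np.nan, np.nan, np.nan)
    )
    return GeneAssociationResult(
        gene_id=gene_id,
        chrom=str(meta.get("chrom", "")),
        n_snps=int(meta.get("n_snps", 0)),
        beta=float(beta),
        se=float(se),
        p=float(p),
        significant=bool(fit.converged and p < cfg.alpha_gene),
        converged=fit.converged,
        conditioned_on=conditioned_on,
        gene_name=str(meta.get("gene_name", gene_id)),
        start=int(meta.get("start", 0)),
    )


def gene_scan(
    scores: GeneScoreMatrix, cov: CovariateTable, cfg: ScanConfig = ScanConfig()
) -> list[GeneAssociationResult]:
    """Marginal scan: one logistic fit per gene with design
    [intercept, gene score, covariates].  Results are ordered by genomic
    position; non-converged genes are carried with their flag."""
    aligned_scores, y, covt = _aligned_design(scores, cov, cfg.covariates)
    covariate_block = covt[list(cfg.covariates)].to_numpy(float)
    results = []
    for gene_id in aligned_scores.columns:
        X = np.column_stack([aligned_scores[gene_id].to_numpy(), covariate_block])
        try:
            fit = fit_logistic(y, X, ["score"] + list(cfg.covariates))
        except CollinearColumnsError as exc:
            logger.warning("gene %s: %s", gene_id, exc)
            fit = LogisticFit(np.array([np.nan]), np.array([np.nan]), np.array([np.nan]),
                              ["score"], False)
        results.append(_result_from_fit(fit, gene_id, scores.gene_info, cfg, ()))
    return _position_sorted(results)


def conditional_scan(
    scores: GeneScoreMatrix, cov: CovariateTable, cfg: ScanConfig
) -> list[GeneAssociationResult]:
    """Re-scan with the condition genes' scores added as covariates.

    The condition genes themselves are excluded from the scanned list; a
    missing condition gene raises.
    """
    if not cfg.condition_genes:
        raise ValueError("conditional_scan requires at least one condition gene")
    absent = [g for g in cfg.condition_genes if g not in scores.scores.columns]
    if absent:
        raise ValueError(f"condition gene(s) absent from score matrix: {', '.join(absent)}")
    aligned_scores, y, covt = _aligned_design(scores, cov, cfg.covariates)
    covariate_block = covt[list(cfg.covariates)].to_numpy(float)
    condition_block = aligned_scores[list(cfg.condition_genes)].to_numpy(float)
    conditioned_on = tuple(cfg.condition_genes)
    results = []
    for gene_id in aligned_scores.columns:
        if gene_id in cfg.condition_genes:
            continue
        X = np.column_stack([
            aligned_scores[gene_id].to_numpy(), condition_block, covariate_block
        ])
        names = ["score"] + [f"cond_{g}" for g in cfg.condition_genes] + list(cfg.covariates)
        try:
            fit = fit_logistic(y, X, names)
        except CollinearColumnsError as exc:
            logger.warning("gene %s (conditional): %s", gene_id, exc)
            fit = LogisticFit(np.array([np.nan]), np.array([np.nan]), np.array([np.nan]),
                              names, False)
        results.append(_result_from_fit(fit, gene_id, scores.gene_info, cfg, conditioned_on))
    return _position_sorted(results)


def _position_sorted(results: list[GeneAssociationResult]) -> list[GeneAssociationResult]:
    def key(r: GeneAssociationResult):
        c = r.chrom.removeprefix("chr")
        return ((int(c), "") if c.isdigit() else (10**6, c), r.start, r.gene_id)

    return sorted(results, key=key)


def results_frame(results: list[GeneAssociationResult]) -> pd.DataFrame:
    rows = [{
        "chrom": r.chrom, "start": r.start, "gene_id": r.gene_id, "gene_name": r.gene_name,
        "n_snps": r.n_snps, "beta": r.beta, "se": r.se, "p": r.p,
        "significant": r.significant, "converged": r.converged,
    } for r in results]
    return pd.DataFrame(rows, columns=["chrom", "start", "gene_id", "gene_name", "n_snps",
                                       "beta", "se", "p", "significant", "converged"])


def assemble_results(
    marginal: list[GeneAssociationResult],
    conditional: list[list[GeneAssociationResult]] = (),
) -> pd.DataFrame:
    """Wide results table: the marginal beta/se/p per gene plus one
    beta/se/p/significant block per conditioning set (suffixed with the
    condition gene names).  Condition genes get NA in their own block."""
    table = results_frame(marginal).set_index("gene_id")
    for cond_results in conditional:
        if not cond_results:
            continue
        suffix = "cond_" + "+".join(cond_results[0].conditioned_on)
        block = results_frame(cond_results).set_index("gene_id")
        block = block[["beta", "se", "p", "significant", "converged"]]
        block.columns = [f"{c}_{suffix}" for c in block.columns]
        table = table.join(block, how="left")
    return _reorder_result_columns(table.reset_index())


def _reorder_result_columns(df: pd.DataFrame) -> pd.DataFrame:
    base = ["chrom", "start", "gene_id", "gene_name", "n_snps", "beta", "se", "p",
            "significant", "converged"]
    rest = [c for c in df.columns if c not in base]
    return df[base + rest]
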