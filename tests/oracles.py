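"""Independent reference computations used to check the implementation.

Everything here deliberately avoids the code paths under test: the HWE
oracle enumerates the conditional heterozygote distribution from the
closed-form log-gamma expression, the logistic oracle maximizes the
likelihood with scipy's generic optimizer, and the gene-score oracle is a
direct dense linear-algebra evaluation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln


def hwe_enumeration_pvalue(n0: int, n1: int, n2: int) -> float:
    """Exact two-sided HWE p-value by full enumeration.

    P(h hets | n, rare allele count r) = n! r! c! 2^h / (n0! h! n2! (2n)!)
    over all het counts h with the parity of r; the p-value sums the
    probabilities no larger than the observed one.
    """
    n = n0 + n1 + n2
    rare = min(n1 + 2 * n0, n1 + 2 * n2)
    common = 2 * n - rare
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(hets + 1) - gammaln(hom_c + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1) + gammaln(common + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n1)]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def logistic_mle(y: np.ndarray, X: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Maximum-likelihood logistic coefficients (intercept first) via
    scipy's BFGS on the exact negative log-likelihood and gradient."""
    y = np.asarray(y, float)
    design = np.column_stack([np.ones(len(y)), np.atleast_2d(np.asarray(X, float))])

    def nll_grad(b):
        eta = design @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        nll = -(y * eta - np.logaddexp(0.0, eta)).sum()
        return nll, -design.T @ (y - mu)

    res = minimize(nll_grad, np.zeros(design.shape[1]), jac=True, method="BFGS",
                   options={"gtol": tol, "maxiter": 500})
    return res.x


def logistic_is_divergent(y: np.ndarray, x: np.ndarray) -> bool:
    """Certify that the simple-logistic MLE lies at infinity: the profile
    likelihood keeps improving as the slope grows without bound."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)

    def best_nll_at_slope(b1: float) -> float:
        from scipy.optimize import minimize_scalar

        def nll(b0):
            eta = b0 + b1 * x
            return -(y * eta - np.logaddexp(0.0, eta)).sum()

        return minimize_scalar(nll, bounds=(-50, 50), method="bounded").fun

    lls = [best_nll_at_slope(b) for b in (1.0, 5.0, 25.0, 125.0)]
    return all(b <= a + 1e-9 for a, b in zip(lls, lls[1:]))


def dense_polaris_scores(G: np.ndarray, betas: np.ndarray, k: float) -> np.ndarray:
    """Direct dense evaluation of the LD-adjusted gene score,
    (G - mean) (R + kI)^{-1} beta with R the genotype correlation matrix."""
    G = np.asarray(G, float)
    Gc = G - G.mean(axis=0)
    sd = G.std(axis=0)
    R = np.corrcoef(G, rowvar=False)
    R = np.atleast_2d(R)
    w = np.linalg.solve(R + k * np.eye(R.shape[0]), np.asarray(betas, float))
    return Gc @ w


def brute_force_window_assignment(variants, windows) -> set:
    """Naive double-loop SNP-to-window assignment.

    ``variants``: VariantRecord list; ``windows``: DataFrame with gene_id,
    chrom, window_start, window_end (1-based closed intervals).  Returns the
    set of (variant_id, gene_id) pairs.
    """
    pairs = set()
    for w in windows.itertuples():
        for v in variants:
            if v.chrom == w.chrom and w.window_start <= v.pos <= w.window_end:
                pairs.add((v.id, w.gene_id))
    return pairs
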