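"""Synthetic two-cohort case-control study generator.

Emulates the study design the pipeline targets: a *discovery* cohort whose
per-SNP logistic-regression results play the role of external GWAS summary
statistics, and an independent *target* cohort with individual-level
genotypes on which per-gene risk scores are computed.  Both cohorts are
drawn from the same population model:

* genotypes from latent-Gaussian AR(1) LD blocks (adjacent-SNP latent
  correlation ``rho``, so the LD matrix fed to the score is controlled
  exactly at the haplotype level),
* an optional two-subpopulation allele-frequency divergence (Balding-
  Nichols ``fst``) generating genuine principal-component structure,
* a liability-threshold phenotype with a configurable set of causal genes,
* imputation uncertainty as genotype-probability triples with per-SNP
  INFO scores,
* covariates (age, sex, genotype-derived PCs).

All randomness flows from one master seed through named substreams, so
identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .io_formats import (
    MISSING,
    CovariateTable,
    DosageSet,
    GeneModelSet,
    GenotypeMatrix,
    SummaryStats,
    VariantRecord,
)

# non-ambiguous allele pairs only (A/T and C/G SNPs cannot be strand-resolved
# during harmonization and would silently shrink genes)
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_STREAMS = {
    "frequencies": 11,
    "alleles": 12,
    "target": 21,
    "discovery": 22,
    "phenotypes-target": 31,
    "phenotypes-discovery": 32,
    "covariates-target": 41,
    "covariates-discovery": 42,
    "noise": 51,
    "pca": 61,
}


@dataclass(frozen=True)
class LDBlockSpec:
    """One LD block: ``n_snps`` SNPs whose latent Gaussians follow an AR(1)
    with adjacent correlation ``rho`` (r_ij = rho^|i-j|); per-SNP MAFs are
    drawn uniformly from ``maf_range``."""

    n_snps: int
    rho: float
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("LD block needs at least one SNP")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")


@dataclass(frozen=True)
class CausalGeneSpec:
    """Marks one gene (by block index) as causal: ``n_causal`` of its SNPs
    carry a per-allele liability effect ``effect_size`` with the given signs
    (default all +1)."""

    gene_index: int
    n_causal: int
    effect_size: float
    direction: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_causal < 1:
            raise ValueError("n_causal must be >= 1")
        if self.direction is not None and len(self.direction) != self.n_causal:
            raise ValueError("direction must list one sign per causal SNP")


def _default_blocks() -> list[LDBlockSpec]:
    return [LDBlockSpec(n_snps=10, rho=0.7) for _ in range(20)]


@dataclass
class SimConfig:
    """Full specification of a synthetic two-cohort study."""

    seed: int
    n_target: int = 2000
    n_discovery: int = 4000
    case_fraction: float = 0.3
    blocks: list[LDBlockSpec] = field(default_factory=_default_blocks)
    causal: list[CausalGeneSpec] = field(default_factory=list)
    snp_spacing: int = 1000
    block_gap: int = 100_000
    age_mean: float = 75.0
    age_sd: float = 8.0
    n_pcs: int = 3
    fst: float = 0.01
    pc_liability: float = 0.5
    dosage_noise: float = 0.1
    dirichlet_conc: float = 10.0
    include_overlap_gene: bool = True
    include_filtered_genes: bool = True
    second_chrom: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_target", "n_discovery", "snp_spacing", "block_gap", "n_pcs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")
        if not (0.0 <= self.dosage_noise <= 1.0):
            raise ValueError("dosage_noise must be in [0, 1]")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        if not self.blocks:
            raise ValueError("at least one LD block is required")
        for spec in self.causal:
            if not (0 <= spec.gene_index < len(self.blocks)):
                raise ValueError(f"causal gene index {spec.gene_index} out of range")
            if spec.n_causal > self.blocks[spec.gene_index].n_snps:
                raise ValueError(
                    f"gene {spec.gene_index}: n_causal {spec.n_causal} exceeds its "
                    f"{self.blocks[spec.gene_index].n_snps} SNPs"
                )

    @property
    def n_snps(self) -> int:
        return sum(b.n_snps for b in self.blocks)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])


# ---------------------------------------------------------------------------
# layout: positions, alleles, frequencies
# ---------------------------------------------------------------------------


def _block_offsets(config: SimConfig) -> list[int]:
    offsets, off = [], 0
    for b in config.blocks:
        offsets.append(off)
        off += b.n_snps
    return offsets


def _block_chrom(config: SimConfig, block_index: int) -> str:
    if config.second_chrom and len(config.blocks) > 1 and block_index == len(config.blocks) - 1:
        return "2"
    return "1"


def _snp_positions(config: SimConfig) -> np.ndarray:
    """bp position of every SNP; positions restart on the second chromosome."""
    pos = np.empty(config.n_snps, dtype=np.int64)
    cursor = {"1": 1, "2": 1}
    for b, (spec, off) in enumerate(zip(config.blocks, _block_offsets(config))):
        chrom = _block_chrom(config, b)
        start = cursor[chrom]
        pos[off : off + spec.n_snps] = start + np.arange(spec.n_snps) * config.snp_spacing
        cursor[chrom] = start + spec.n_snps * config.snp_spacing + config.block_gap
    return pos


def variant_records(config: SimConfig) -> list[VariantRecord]:
    """The shared variant map for both cohorts (ids, positions, alleles)."""
    rng = config.rng("alleles")
    positions = _snp_positions(config)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=config.n_snps)
    records = []
    j = 0
    for b, spec in enumerate(config.blocks):
        chrom = _block_chrom(config, b)
        for _ in range(spec.n_snps):
            a1, a2 = _ALLELE_PAIRS[pair_idx[j]]
            records.append(VariantRecord(f"rs{j + 1:06d}", chrom, int(positions[j]), a1, a2))
            j += 1
    return records


def _allele_frequencies(config: SimConfig) -> np.ndarray:
    """Per-subpopulation a1 allele frequencies, shape (2, n_snps).

    Ancestral MAFs are uniform within each block's range; the two
    subpopulations diverge by a Balding-Nichols Beta draw at the
    configured fst (fst = 0 collapses to a single population).
    """
    rng = config.rng("frequencies")
    p = np.empty(config.n_snps)
    for spec, off in zip(config.blocks, _block_offsets(config)):
        low, high = spec.maf_range
        p[off : off + spec.n_snps] = rng.uniform(low, high, size=spec.n_snps)
    if config.fst == 0.0:
        return np.vstack([p, p])
    scale = (1.0 - config.fst) / config.fst
    sub = rng.beta(p * scale, (1.0 - p) * scale, size=(2, config.n_snps))
    return np.clip(sub, 1e-4, 1 - 1e-4)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(config: SimConfig, cohort: str) -> GenotypeMatrix:
    """Draw true genotypes for one cohort by latent-Gaussian thresholding.

    Per block, each haplotype's latent vector is AR(1) with the block's
    rho; the haplotype carries the a1 allele where the latent value falls
    below the per-SNP quantile of its frequency.  The two cohorts use
    independent random substreams of the master seed but share the
    population's frequencies and LD structure.
    """
    if cohort not in ("target", "discovery"):
        raise ValueError(f"cohort must be 'target' or 'discovery', got {cohort!r}")
    n = config.n_target if cohort == "target" else config.n_discovery
    rng = config.rng(cohort)
    freqs = _allele_frequencies(config)
    subpop = (np.arange(n) >= n // 2).astype(int)  # half/half split
    thresholds = norm.ppf(freqs)  # (2, n_snps)
    calls = np.empty((n, config.n_snps), dtype=np.int8)
    for spec, off in zip(config.blocks, _block_offsets(config)):
        m = spec.n_snps
        e = rng.standard_normal((n, 2, m))
        z = np.empty_like(e)
        z[:, :, 0] = e[:, :, 0]
        decay = np.sqrt(1.0 - spec.rho**2)
        for j in range(1, m):
            z[:, :, j] = spec.rho * z[:, :, j - 1] + decay * e[:, :, j]
        t = thresholds[subpop, off : off + m]  # (n, m)
        alleles = z < t[:, None, :]
        calls[:, off : off + m] = alleles.sum(axis=1)
    prefix = "T" if cohort == "target" else "D"
    samples = [f"{prefix}{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(samples, variant_records(config), calls)


def causal_snp_indices(config: SimConfig) -> list[tuple[int, float]]:
    """Flat (snp_index, signed per-allele liability effect) pairs implied by
    the causal gene specs; causal SNPs are spread evenly within the block."""
    offsets = _block_offsets(config)
    out = []
    for spec in config.causal:
        block = config.blocks[spec.gene_index]
        picks = np.linspace(0, block.n_snps - 1, spec.n_causal).round().astype(int)
        picks = np.unique(picks)
        signs = spec.direction or tuple([1] * spec.n_causal)
        for k, local in enumerate(picks):
            out.append((offsets[spec.gene_index] + int(local), signs[k] * spec.effect_size))
    return out


def genotype_pcs(gm: GenotypeMatrix, n_pcs: int, seed: int) -> np.ndarray:
    """Top principal components of the centered genotype matrix,
    standardized to mean 0 / sd 1 (the usual GWAS population covariates)."""
    from sklearn.decomposition import PCA

    x = gm.calls.astype(np.float64)
    x -= x.mean(axis=0)
    n_pcs = min(n_pcs, min(x.shape) - 1)
    if n_pcs < 1:
        return np.zeros((x.shape[0], 0))
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed % (2**31))
    scores = pca.fit_transform(x)
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    return scores / sd


def simulate_phenotypes(
    gm: GenotypeMatrix, config: SimConfig, cohort: str = "target"
) -> CovariateTable:
    """Liability-threshold phenotypes plus covariates for one cohort.

    Liability = sum of causal per-allele effects + pc_liability * PC1 +
    standard-normal noise; samples above the empirical (1 - case_fraction)
    liability quantile are cases.
    """
    rng = config.rng(f"phenotypes-{cohort}")
    cov_rng = config.rng(f"covariates-{cohort}")
    n = gm.n_samples
    liability = rng.standard_normal(n)
    for snp_idx, beta in causal_snp_indices(config):
        liability += beta * gm.calls[:, snp_idx].astype(np.float64)
    pcs = genotype_pcs(gm, config.n_pcs, config.seed)
    if config.pc_liability != 0.0 and pcs.shape[1] >= 1:
        liability += config.pc_liability * pcs[:, 0]
    cut = np.quantile(liability, 1.0 - config.case_fraction)
    phenotype = (liability > cut).astype(int)
    table = pd.DataFrame({
        "sample_id": gm.samples,
        "phenotype": phenotype,
        "age": cov_rng.normal(config.age_mean, config.age_sd, size=n).round(1),
        "sex": cov_rng.integers(0, 2, size=n),
    })
    for k in range(pcs.shape[1]):
        table[f"PC{k + 1}"] = pcs[:, k]
    return CovariateTable(table)


# ---------------------------------------------------------------------------
# discovery summary statistics
# ---------------------------------------------------------------------------


def batched_single_snp_logistic(
    g: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-10
) -> pd.DataFrame:
    """Per-SNP logistic regression phenotype ~ intercept + genotype, fitted
    by Newton's method simultaneously across SNPs.

    Returns a frame with beta, se, p (Wald, standard normal) and ok.
    Monomorphic SNPs: beta 0, se +inf, p 1, ok False.  Diverging fits
    (perfect separation): beta/p NaN, se +inf, ok False.
    """
    g = np.asarray(g, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = g.shape
    beta = np.zeros(m)
    se = np.full(m, np.inf)
    p = np.full(m, np.nan)
    ok = np.zeros(m, dtype=bool)
    mono = g.std(axis=0) == 0
    p[mono] = 1.0
    ybar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    chunk = 512
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        cols = np.arange(lo, hi)[~mono[lo:hi]]
        if cols.size == 0:
            continue
        gc = g[:, cols]
        b0 = np.full(cols.size, logit(ybar))
        b1 = np.zeros(cols.size)
        converged = np.zeros(cols.size, dtype=bool)
        for _ in range(max_iter):
            mu = expit(b0[None, :] + gc * b1[None, :])
            w = mu * (1.0 - mu)
            r = y[:, None] - mu
            s0 = r.sum(axis=0)
            s1 = (gc * r).sum(axis=0)
            h00 = w.sum(axis=0)
            h01 = (w * gc).sum(axis=0)
            h11 = (w * gc * gc).sum(axis=0)
            det = h00 * h11 - h01 * h01
            det = np.where(det <= 0, np.nan, det)
            d0 = (h11 * s0 - h01 * s1) / det
            d1 = (h00 * s1 - h01 * s0) / det
            step = np.nan_to_num(np.maximum(np.abs(d0), np.abs(d1)), nan=np.inf)
            live = ~converged
            b0[live] += np.nan_to_num(d0[live])
            b1[live] += np.nan_to_num(d1[live])
            converged |= step < tol
            if converged.all():
                break
        mu = expit(b0[None, :] + gc * b1[None, :])
        w = mu * (1.0 - mu)
        h00 = w.sum(axis=0)
        h01 = (w * gc).sum(axis=0)
        h11 = (w * gc * gc).sum(axis=0)
        det = h00 * h11 - h01 * h01
        with np.errstate(invalid="ignore", divide="ignore"):
            var1 = np.where(det > 0, h00 / det, np.inf)
        good = converged & np.isfinite(var1) & (np.abs(b1) < 15.0)
        from scipy.stats import norm as _norm

        beta[cols[good]] = b1[good]
        se[cols[good]] = np.sqrt(var1[good])
        p[cols[good]] = 2.0 * _norm.sf(np.abs(b1[good]) / np.sqrt(var1[good]))
        ok[cols[good]] = True
        beta[cols[~good]] = np.nan
    p = np.where(ok, np.clip(p, np.finfo(float).tiny, 1.0), p)
    return pd.DataFrame({"beta": beta, "se": se, "p": p, "ok": ok})


def make_discovery_summary_stats(gm: GenotypeMatrix, cov: CovariateTable) -> SummaryStats:
    """Single-variant logistic scan of the discovery cohort, packaged as the
    external summary statistics that weight the gene scores.  The effect
    allele is each variant's a1."""
    order = {s: i for i, s in enumerate(gm.samples)}
    y = cov.table.set_index("sample_id").loc[gm.samples, "phenotype"].to_numpy(float)
    del order
    g = gm.calls_float()
    col_means = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_means, inds[1])
    fits = batched_single_snp_logistic(g, y)
    table = pd.DataFrame({
        "id": [v.id for v in gm.variants],
        "chrom": [v.chrom for v in gm.variants],
        "pos": [v.pos for v in gm.variants],
        "effect_allele": [v.a1 for v in gm.variants],
        "other_allele": [v.a2 for v in gm.variants],
        "beta": fits["beta"].to_numpy(),
        "se": fits["se"].to_numpy(),
        "p": fits["p"].to_numpy(),
        "ok": fits["ok"].to_numpy(),
    })
    return SummaryStats(table)


# ---------------------------------------------------------------------------
# imputation noise
# ---------------------------------------------------------------------------


def add_imputation_noise(gm: GenotypeMatrix, eta: float, seed: int,
                         concentration: float = 10.0) -> DosageSet:
    """Blur true genotypes into probability triples and attach INFO scores.

    Each triple is (1 - eta) x a unit mass on the true genotype + eta x a
    symmetric Dirichlet(concentration) draw.  INFO is the share of the
    dosage variance that reflects real genotype signal,
    Var(dosage) / (Var(dosage) + mean per-sample genotype uncertainty),
    which is 1 exactly in the no-noise limit and tends to 0 as eta -> 1.
    """
    if not (0.0 <= eta <= 1.0):
        raise ValueError(f"noise level eta must be in [0, 1], got {eta}")
    rng = np.random.default_rng([_STREAMS["noise"], seed])
    n, m = gm.calls.shape
    probs = np.zeros((n, m, 3))
    calls = gm.calls
    if (calls == MISSING).any():
        raise ValueError("imputation noise expects fully observed true genotypes")
    onehot = np.eye(3)[calls]
    if eta == 0.0:
        probs = onehot
    else:
        noise = rng.dirichlet([concentration] * 3, size=(n, m))
        probs = (1.0 - eta) * onehot + eta * noise
    dosage = probs[:, :, 1] + 2.0 * probs[:, :, 2]
    e2 = probs[:, :, 1] + 4.0 * probs[:, :, 2]
    per_sample_var = e2 - dosage**2
    signal = dosage.var(axis=0)
    uncertainty = per_sample_var.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        info = np.where(signal + uncertainty > 0, signal / (signal + uncertainty), 1.0)
    info = np.clip(info, 0.0, 1.0)
    variants = [dataclasses.replace(v, info=float(i)) for v, i in zip(gm.variants, info)]
    return DosageSet(list(gm.samples), variants, probs)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def make_gene_models(config: SimConfig) -> tuple[GeneModelSet, pd.DataFrame]:
    """Gene records tiling the simulated SNP space, plus a truth table.

    One protein-coding KNOWN gene spans each LD block (strands alternate).
    Optionally adds: a protein-coding gene overlapping the second half of
    block 0 (to exercise multi-gene SNP assignment), one lincRNA gene and
    one NOVEL-status gene (to exercise the gene-model filter).
    """
    positions = _snp_positions(config)
    offsets = _block_offsets(config)
    causal_blocks = {c.gene_index for c in config.causal}
    rows, truth = [], []
    for b, spec in enumerate(config.blocks):
        first = int(positions[offsets[b]])
        last = int(positions[offsets[b] + spec.n_snps - 1])
        gid = f"GENE{b + 1:04d}"
        rows.append({
            "gene_id": gid, "gene_name": gid, "chrom": _block_chrom(config, b),
            "strand": "+" if b % 2 == 0 else "-", "start": first, "end": last,
            "biotype": "protein_coding", "status": "KNOWN",
        })
        truth.append({"gene_id": gid, "causal": b in causal_blocks})
    if config.include_overlap_gene and config.blocks[0].n_snps >= 2:
        half = offsets[0] + config.blocks[0].n_snps // 2
        rows.append({
            "gene_id": "GENE_OVL", "gene_name": "GENE_OVL", "chrom": _block_chrom(config, 0),
            "strand": "+", "start": int(positions[half]),
            "end": int(positions[offsets[0] + config.blocks[0].n_snps - 1]),
            "biotype": "protein_coding", "status": "KNOWN",
        })
        truth.append({"gene_id": "GENE_OVL", "causal": False})
    if config.include_filtered_genes:
        b = min(1, len(config.blocks) - 1)
        first = int(positions[offsets[b]])
        last = int(positions[offsets[b] + config.blocks[b].n_snps - 1])
        chrom = _block_chrom(config, b)
        rows.append({"gene_id": "GENE_LNC", "gene_name": "GENE_LNC", "chrom": chrom,
                     "strand": "+", "start": first, "end": last,
                     "biotype": "lincRNA", "status": "KNOWN"})
        rows.append({"gene_id": "GENE_NOV", "gene_name": "GENE_NOV", "chrom": chrom,
                     "strand": "-", "start": first, "end": last,
                     "biotype": "protein_coding", "status": "NOVEL"})
        truth += [{"gene_id": "GENE_LNC", "causal": False},
                  {"gene_id": "GENE_NOV", "causal": False}]
    genes = GeneModelSet(pd.DataFrame(rows))
    truth_df = pd.DataFrame(truth)
    causal_ids = {f"GENE{b + 1:04d}" for b in causal_blocks}
    snp_lists = {gid: [] for gid in causal_ids}
    variants = variant_records(config)
    for snp_idx, _ in causal_snp_indices(config):
        for c in config.causal:
            off = offsets[c.gene_index]
            if off <= snp_idx < off + config.blocks[c.gene_index].n_snps:
                snp_lists[f"GENE{c.gene_index + 1:04d}"].append(variants[snp_idx].id)
    truth_df["causal_snps"] = truth_df["gene_id"].map(
        lambda g: ",".join(dict.fromkeys(snp_lists.get(g, [])))
    )
    return genes, truth_df


# ---------------------------------------------------------------------------
# one-call study bundle
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """Everything one simulated study produces."""

    config: SimConfig
    target_truth: GenotypeMatrix
    target_dosages: DosageSet
    target_covariates: CovariateTable
    discovery_genotypes: GenotypeMatrix
    discovery_covariates: CovariateTable
    summary_stats: SummaryStats
    genes: GeneModelSet
    truth: pd.DataFrame


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Run the full generator: two cohorts, phenotypes, summary statistics,
    dosages with imputation noise, gene models and the causal truth table."""
    target = simulate_genotypes(config, "target")
    discovery = simulate_genotypes(config, "discovery")
    target_cov = simulate_phenotypes(target, config, "target")
    discovery_cov = simulate_phenotypes(discovery, config, "discovery")
    sumstats = make_discovery_summary_stats(discovery, discovery_cov)
    dosages = add_imputation_noise(target, config.dosage_noise, config.seed,
                                   config.dirichlet_conc)
    genes, truth = make_gene_models(config)
    return SyntheticStudy(config, target, dosages, target_cov, discovery,
                          discovery_cov, sumstats, genes, truth)


def write_fixture_set(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the study to disk in the pipeline's standard file formats."""
    from . import io_formats as iof

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plink_prefix": outdir / "target",
        "vcf": outdir / "target.vcf",
        "summary_stats": outdir / "discovery_sumstats.tsv",
        "gtf": outdir / "genes.gtf",
        "covariates": outdir / "target_covariates.tsv",
        "truth": outdir / "truth.tsv",
    }
    iof.write_plink(study.target_truth, paths["plink_prefix"])
    iof.write_vcf(study.target_dosages, paths["vcf"])
    iof.write_summary_stats(study.summary_stats, paths["summary_stats"])
    iof.write_gtf(study.genes, paths["gtf"])
    iof.write_covariates(study.target_covariates, paths["covariates"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
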