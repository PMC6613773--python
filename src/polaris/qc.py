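"""Variant quality control: hard-calling and the four standard filters.

Imputed genotype probabilities are converted to the most probable genotype
when that probability reaches the hard-call threshold (default 0.9), else
set missing.  Variants are then removed if ANY of these fails:

* imputation INFO score < 0.4 (exactly 0.4 keeps),
* minor allele frequency < 0.01 (exactly 0.01 keeps),
* genotype missingness >= 0.05 (exactly 0.05 removes),
* Hardy-Weinberg exact-test p < 1e-6 (computed in controls by default).

Boundary semantics follow the printed inequalities exactly.  The HWE test
is the exact conditional test (full enumeration of heterozygote counts
given allele counts, two-sided by probability ordering, no mid-p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, DosageSet, GenotypeMatrix

FILTER_ORDER = ("info", "maf", "missingness", "hwe")


@dataclass(frozen=True)
class QCThresholds:
    hardcall_prob: float = 0.9
    info_min: float = 0.4
    maf_min: float = 0.01
    missing_max: float = 0.05
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("hardcall_prob", "info_min", "maf_min", "missing_max", "hwe_p_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0) and not (name == "hardcall_prob" and v == 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.hardcall_prob <= 1.0 / 3.0:
            raise ValueError("hardcall_prob must exceed 1/3 for the argmax rule to be unique")


@dataclass
class QCReport:
    """Bookkeeping of which variants survived which filter."""

    status: pd.DataFrame  # variant id, kept, first_fail
    counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_kept: int = 0

    def __post_init__(self) -> None:
        if self.n_kept + sum(self.counts.values()) != self.n_input:
            raise ValueError("QC report counts do not reconcile with input total")

    def to_frame(self) -> pd.DataFrame:
        return self.status


def hard_call(dosages: DosageSet, threshold: float = 0.9) -> GenotypeMatrix:
    """Convert probability triples to most-probable genotypes.

    The call is the argmax genotype when its probability is >= threshold
    (boundary inclusive), otherwise missing.  Equal-probability ties at or
    above the threshold resolve to the lower genotype count.
    """
    if not (1.0 / 3.0 < threshold <= 1.0):
        raise ValueError(f"hard-call threshold must be in (1/3, 1], got {threshold}")
    probs = dosages.probs
    best = probs.argmax(axis=2)  # argmax takes the first (lowest) genotype on ties
    top = np.take_along_axis(probs, best[:, :, None], axis=2)[:, :, 0]
    calls = np.where(top >= threshold - 1e-12, best, MISSING).astype(np.int8)
    return GenotypeMatrix(list(dosages.samples), list(dosages.variants), calls)


def minor_allele_frequency(calls: np.ndarray) -> float:
    """MAF of one variant's genotype column (missing-aware denominator)."""
    calls = np.asarray(calls)
    obs = calls[calls != MISSING]
    if obs.size == 0:
        raise ValueError("cannot compute MAF: all genotypes missing")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def genotype_missingness(calls: np.ndarray) -> float:
    calls = np.asarray(calls)
    return float((calls == MISSING).mean())


def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts (0/1/2 copies
    of an allele).

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than the observed
    one (no mid-p correction).  Monomorphic data returns 1 by convention.
    """
    if min(n0, n1, n2) < 0 or n0 + n1 + n2 < 1:
        raise ValueError("genotype counts must be non-negative with at least one sample")
    n = n0 + n1 + n2
    rare = min(n1 + 2 * n0, n1 + 2 * n2)  # minor allele copies
    if rare == 0:
        return 1.0
    # conditional distribution of the het count via the standard recurrence;
    # het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(hets.size)
    # start from the largest het count and recurse downward:
    # P(h-2)/P(h) = h*(h-1) / (4*(hom_r+1)*(hom_c+1)) with hom counts at h
    probs[-1] = 1.0
    for idx in range(hets.size - 1, 0, -1):
        h = hets[idx]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[idx - 1] = probs[idx] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        if probs[idx - 1] > 1e250:  # rescale to keep the recurrence finite
            probs[idx - 1:] *= 1e-250
    probs /= probs.sum()
    obs_p = probs[np.searchsorted(hets, n1)]
    return float(min(1.0, probs[probs <= obs_p * (1 + 1e-12)].sum()))


def apply_variant_filters(
    gm: GenotypeMatrix,
    info: np.ndarray | None,
    thresholds: QCThresholds = QCThresholds(),
    hwe_subset: str = "controls",
    phenotype: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the four variant filters and report per-filter exclusions.

    A variant is removed if any filter fails; ``first_fail`` attributes each
    exclusion to the first failing filter in the fixed order
    info -> maf -> missingness -> hwe (attribution only — the kept set does
    not depend on the order).  ``info=None`` skips the INFO filter (hard-
    call-only inputs carry no imputation metadata).  HWE is computed in
    controls by default (``hwe_subset='all'`` uses everyone), which
    requires an aligned 0/1 ``phenotype`` vector.
    """
    if info is not None:
        info = np.asarray(info, dtype=float)
        if info.shape != (gm.n_variants,):
            raise ValueError(
                f"info vector length {info.shape} does not match {gm.n_variants} variants"
            )
    if hwe_subset not in ("controls", "all"):
        raise ValueError("hwe_subset must be 'controls' or 'all'")
    if hwe_subset == "controls":
        if phenotype is None:
            raise ValueError("controls-only HWE requires the phenotype vector")
        phenotype = np.asarray(phenotype)
        if phenotype.shape != (gm.n_samples,):
            raise ValueError("phenotype length does not match sample count")
        hwe_rows = phenotype == 0
    else:
        hwe_rows = np.ones(gm.n_samples, dtype=bool)

    first_fail = np.array([""] * gm.n_variants, dtype=object)
    kept = np.ones(gm.n_variants, dtype=bool)
    counts = {name: 0 for name in FILTER_ORDER}
    hwe_calls = gm.calls[hwe_rows]
    for j in range(gm.n_variants):
        col = gm.calls[:, j]
        fails = []
        if info is not None and not np.isnan(info[j]) and info[j] < thresholds.info_min:
            fails.append("info")
        obs = col[col != MISSING]
        if obs.size == 0 or minor_allele_frequency(col) < thresholds.maf_min:
            fails.append("maf")
        if genotype_missingness(col) >= thresholds.missing_max:
            fails.append("missingness")
        sub = hwe_calls[:, j]
        n_geno = [(sub == k).sum() for k in (0, 1, 2)]
        if sum(n_geno) >= 1 and hwe_exact_test(*n_geno) < thresholds.hwe_p_min:
            fails.append("hwe")
        if fails:
            kept[j] = False
            first_fail[j] = fails[0]
            counts[fails[0]] += 1
    status = pd.DataFrame({
        "id": gm.variant_ids(),
        "kept": kept,
        "first_fail": first_fail,
    })
    report = QCReport(status=status, counts=counts, n_input=gm.n_variants,
                      n_kept=int(kept.sum()))
    return gm.subset_variants(kept), report


def write_qc_report(report: QCReport, path) -> None:
    """Per-variant status TSV plus a summary comment header."""
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# variants_in={report.n_input}\tvariants_kept={report.n_kept}\n")
        for name in FILTER_ORDER:
            fh.write(f"# excluded_{name}={report.counts.get(name, 0)}\n")
    report.status.to_csv(path, sep="\t", index=False, mode="a")
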