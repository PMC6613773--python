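"""File formats and in-memory containers for the gene-score pipeline.

Genotypes enter either as hard calls (:class:`GenotypeMatrix`) or as
genotype-probability triples (:class:`DosageSet`); external GWAS effect
sizes as :class:`SummaryStats`; gene annotations as :class:`GeneModelSet`;
sample phenotypes and covariates as :class:`CovariateTable`.  All
downstream modules consume these containers only, so format quirks
(PLINK's 2-bit packing, VCF's GP ordering, GTF's attribute dialect) live
here and nowhere else.

Coordinates are 1-based and fully closed throughout, matching GTF and BIM
conventions.  Genotype calls count copies of the a1 (effect/counted)
allele; ``MISSING`` (-1) marks no-calls.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

_VALID_ALLELES = frozenset("ACGT")


class FormatError(ValueError):
    """Malformed input file or violated container invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV.  ``a1`` is the counted (effect) allele."""

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    info: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant {self.id}: pos {self.pos} < 1")
        for allele in (self.a1, self.a2):
            if allele not in _VALID_ALLELES:
                raise FormatError(
                    f"variant {self.id}: non-SNV allele {allele!r} (only A/C/G/T supported)"
                )
        if self.a1 == self.a2:
            raise FormatError(f"variant {self.id}: identical alleles {self.a1}")
        if self.info is not None and not (0.0 <= self.info <= 1.0):
            raise FormatError(f"variant {self.id}: INFO {self.info} outside [0, 1]")


@dataclass
class GenotypeMatrix:
    """Hard-called genotypes: ``calls[i, j]`` counts copies of variant j's a1
    allele in sample i, with -1 for missing."""

    samples: list[str]
    variants: list[VariantRecord]
    calls: np.ndarray  # int8, (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise FormatError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("genotype calls must be 0/1/2 or MISSING (-1)")
        _check_unique_ids([v.id for v in self.variants], "variant")
        _check_unique_ids(self.samples, "sample")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the variants selected by a boolean or
        integer index array (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        variants = [self.variants[j] for j in keep]
        return GenotypeMatrix(list(self.samples), variants, self.calls[:, keep])

    def calls_float(self) -> np.ndarray:
        """Calls as float64 with missing entries as NaN."""
        out = self.calls.astype(np.float64)
        out[self.calls == MISSING] = np.nan
        return out


@dataclass
class DosageSet:
    """Imputed genotype probabilities: ``probs[i, j]`` is the triple
    (P(0 copies of a1), P(1), P(2)) for sample i at variant j."""

    samples: list[str]
    variants: list[VariantRecord]
    probs: np.ndarray  # float64, (n_samples, n_variants, 3)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (len(self.samples), len(self.variants), 3):
            raise FormatError(
                f"probability array shape {self.probs.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants x 3"
            )
        if self.probs.size:
            if self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-9:
                raise FormatError("genotype probabilities outside [0, 1]")
            sums = self.probs.sum(axis=2)
            if np.abs(sums - 1.0).max() > 1e-6:
                i, j = np.unravel_index(np.abs(sums - 1.0).argmax(), sums.shape)
                raise FormatError(
                    f"genotype probability triple for sample {self.samples[i]} / "
                    f"variant {self.variants[j].id} sums to {sums[i, j]:.6g}, not 1"
                )
        _check_unique_ids([v.id for v in self.variants], "variant")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosages(self) -> np.ndarray:
        """Expected a1 allele count per sample x variant."""
        return self.probs[:, :, 1] + 2.0 * self.probs[:, :, 2]

    def info_scores(self) -> np.ndarray:
        """Per-variant INFO from the variant metadata (NaN where absent)."""
        return np.array(
            [v.info if v.info is not None else np.nan for v in self.variants]
        )


SUMMARY_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"]


@dataclass
class SummaryStats:
    """External GWAS per-SNP effect sizes (the score weights).

    ``table`` columns: id, chrom, pos, effect_allele, other_allele, beta
    (log-odds), se, p, ok.  ``ok=False`` flags monomorphic or non-converged
    fits, whose beta/se/p are sentinels and are excluded downstream.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"summary statistics missing column(s): {', '.join(missing)}")
        if "ok" not in self.table.columns:
            self.table = self.table.assign(ok=True)
        dup = self.table["id"][self.table["id"].duplicated()].unique()
        if len(dup):
            raise FormatError(f"duplicate variant id(s) in summary statistics: {', '.join(dup)}")
        good = self.table[self.table["ok"]]
        bad_se = good[~(good["se"] > 0)]
        if len(bad_se):
            rows = ", ".join(f"{r.id} (se={r.se})" for r in bad_se.itertuples())
            raise FormatError(f"summary statistics rows with se <= 0: {rows}")
        bad_p = good[~((good["p"] > 0) & (good["p"] <= 1))]
        if len(bad_p):
            rows = ", ".join(f"{r.id} (p={r.p})" for r in bad_p.itertuples())
            raise FormatError(f"summary statistics rows with p outside (0, 1]: {rows}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


GENE_COLUMNS = ["gene_id", "gene_name", "chrom", "strand", "start", "end", "biotype", "status"]


@dataclass
class GeneModelSet:
    """Gene records defining score windows (1-based closed intervals)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"gene model table missing column(s): {', '.join(missing)}")
        dup = self.table["gene_id"][self.table["gene_id"].duplicated()].unique()
        if len(dup):
            raise FormatError(f"duplicate gene id(s): {', '.join(dup)}")
        bad = self.table[self.table["start"] > self.table["end"]]
        if len(bad):
            raise FormatError(
                "gene(s) with start > end: " + ", ".join(bad["gene_id"].astype(str))
            )
        bad_strand = set(self.table["strand"]) - {"+", "-"}
        if bad_strand:
            raise FormatError(f"invalid strand value(s): {bad_strand}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CovariateTable:
    """Per-sample phenotype (0 control / 1 case) and covariates.

    ``table`` has a ``sample_id`` column plus ``phenotype``, ``age``,
    ``sex`` and any number of ``PC*`` columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample_id", "phenotype"):
            if col not in self.table.columns:
                raise FormatError(f"covariate table missing column: {col}")
        _check_unique_ids(list(self.table["sample_id"]), "sample")
        if self.table["phenotype"].isna().any():
            raise FormatError("covariate table has missing phenotypes")
        bad = set(self.table["phenotype"].unique()) - {0, 1}
        if bad:
            raise FormatError(f"phenotype values must be 0/1, found {bad}")
        self.table = self.table.reset_index(drop=True)

    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("sample_id", "phenotype")]

    def __len__(self) -> int:
        return len(self.table)


def _check_unique_ids(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise FormatError(f"duplicate {what} id(s): {', '.join(map(str, dups))}")


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"  # v1.00, SNP-major

# 2-bit codes (PLINK 1 .bed): 00 = hom A1 (2 copies of a1), 01 = missing,
# 10 = het, 11 = hom A2 (0 copies of a1).
_CODE_TO_CALL = np.array([2, MISSING, 1, 0], dtype=np.int8)
_CALL_TO_CODE = {2: 0, 1: 2, 0: 3, MISSING: 1}

_BYTE_LUT = np.zeros((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _CODE_TO_CALL[(_b >> (2 * _k)) & 3]


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 bed/bim/fam triplet into a GenotypeMatrix."""
    prefix = Path(prefix)
    bim = _read_bim(Path(str(prefix) + ".bim"))
    fam_samples = _read_fam(Path(str(prefix) + ".fam"))
    bed_path = Path(str(prefix) + ".bed")
    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: not a SNP-major PLINK 1 .bed file")
    n, m = len(fam_samples), len(bim)
    bpv = (n + 3) // 4  # bytes per variant
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bpv * m:
        raise FormatError(
            f"{bed_path}: expected {bpv * m} data bytes for {n} samples x {m} variants, "
            f"found {body.size}"
        )
    decoded = _BYTE_LUT[body.reshape(m, bpv)].reshape(m, bpv * 4)[:, :n]
    return GenotypeMatrix(fam_samples, bim, np.ascontiguousarray(decoded.T))


def _read_bim(path: Path) -> list[VariantRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BIM columns, got {len(parts)}")
            chrom, vid, _cm, pos, a1, a2 = parts
            try:
                records.append(VariantRecord(vid, chrom, int(pos), a1, a2))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    _check_unique_ids([r.id for r in records], "variant")
    return records


def _read_fam(path: Path) -> list[str]:
    samples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 FAM columns")
            samples.append(parts[1])
    return samples


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK 1 bed/bim/fam triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(Path(str(prefix) + ".bim"), "w") as fh:
        for v in gm.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.a1}\t{v.a2}\n")
    with open(Path(str(prefix) + ".fam"), "w") as fh:
        for s in gm.samples:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")
    n = gm.n_samples
    bpv = (n + 3) // 4
    codes = np.empty((gm.n_variants, n), dtype=np.uint8)
    for call, code in _CALL_TO_CODE.items():
        codes[(gm.calls == call).T] = code
    padded = np.zeros((gm.n_variants, bpv * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(Path(str(prefix) + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# VCF (GT and GP)
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> GenotypeMatrix | DosageSet:
    """Read a VCF.  Returns a DosageSet when a GP FORMAT field is present,
    otherwise a GenotypeMatrix from GT.  ALT is the counted (a1) allele.

    Multi-allelic records and non-SNV alleles are rejected.
    """
    import cyvcf2

    path = Path(path)
    vcf = cyvcf2.VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    gp_rows: list[np.ndarray] = []
    gt_rows: list[np.ndarray] = []
    has_gp: bool | None = None
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT)}); split or drop multi-allelics first"
            )
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        info = rec.INFO.get("INFO")
        if info is None:
            info = rec.INFO.get("R2")
        try:
            variants.append(
                VariantRecord(vid, rec.CHROM, rec.POS, rec.ALT[0], rec.REF,
                              float(info) if info is not None else None)
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {rec.CHROM}:{rec.POS}: {exc}") from exc
        gp = rec.format("GP")
        if has_gp is None:
            has_gp = gp is not None
        elif has_gp != (gp is not None):
            raise FormatError(f"{path}: GP field present for some records but not others")
        if has_gp:
            gp = np.asarray(gp, dtype=np.float64)
            if gp.shape != (len(samples), 3):
                raise FormatError(f"{path}: {vid}: GP must carry 3 values per sample")
            sums = gp.sum(axis=1)
            off = np.abs(sums - 1.0)
            if off.max() > 1e-4:
                i = int(off.argmax())
                raise FormatError(
                    f"{path}: {vid}: GP triple for sample {samples[i]} sums to "
                    f"{sums[i]:.4g}, violating probability normalization"
                )
            gp_rows.append(gp / sums[:, None])
        else:
            gts = np.asarray(rec.gt_types)  # gts012: 0/1/2 alt copies, 3 missing
            calls = np.where(gts == 3, MISSING, gts).astype(np.int8)
            gt_rows.append(calls)
    _check_unique_ids([v.id for v in variants], "variant")
    if has_gp:
        probs = (
            np.stack(gp_rows, axis=1) if gp_rows else np.empty((len(samples), 0, 3))
        )
        return DosageSet(samples, variants, probs)
    calls = np.stack(gt_rows, axis=1) if gt_rows else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(samples, variants, calls)


def write_vcf(data: GenotypeMatrix | DosageSet, path: str | Path) -> None:
    """Write genotypes to an uncompressed VCF (GT for hard calls, GT+GP for
    dosages).  a1 is written as ALT; per-variant INFO score as INFO=."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    is_dosage = isinstance(data, DosageSet)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v.chrom for v in data.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation INFO score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if is_dosage:
            fh.write(
                '##FORMAT=<ID=GP,Number=G,Type=Float,Description='
                '"Genotype probabilities P(0),P(1),P(2) copies of ALT">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(data.samples) + "\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, v in enumerate(data.variants):
            info_field = f"INFO={v.info:.6g}" if v.info is not None else "."
            fmt = "GT:GP" if is_dosage else "GT"
            cols = [v.chrom, str(v.pos), v.id, v.a2, v.a1, ".", "PASS", info_field, fmt]
            if is_dosage:
                triples = data.probs[:, j, :]
                best = triples.argmax(axis=1)
                for i in range(len(data.samples)):
                    gp = ",".join(f"{x:.8g}" for x in triples[i])
                    cols.append(f"{gt_strings[int(best[i])]}:{gp}")
            else:
                for i in range(len(data.samples)):
                    cols.append(gt_strings[int(data.calls[i, j])])
            fh.write("\t".join(cols) + "\n")


def read_genotypes(path: str | Path, format: str) -> GenotypeMatrix | DosageSet:
    """Dispatch genotype reading by format ('plink' prefix or 'vcf' file)."""
    if format == "plink":
        return read_plink(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r} (expected 'plink' or 'vcf')")


# ---------------------------------------------------------------------------
# summary statistics TSV
# ---------------------------------------------------------------------------


def read_summary_stats(path: str | Path) -> SummaryStats:
    """Read a tab-separated summary-statistics file.

    Required header columns: id, chrom, pos, effect_allele, other_allele,
    beta, se, p.  An optional ``ok`` column flags usable rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("%s: summary statistics file contains no data rows", path)
    try:
        return SummaryStats(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_summary_stats(ss: SummaryStats, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ss.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# GTF (GENCODE dialect)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"\s*;')
_MANDATORY_ATTRS = ("gene_id", "gene_name", "gene_type", "gene_status")


def read_gene_models(path: str | Path) -> GeneModelSet:
    """Read gene-level records from a GENCODE-dialect GTF.

    Only ``feature == gene`` rows are consumed; transcript/exon rows are
    ignored.  All genes are returned regardless of biotype/status —
    filtering to known protein-coding genes is a separate, testable step
    (:func:`polaris.gene_mapping.filter_gene_models`).
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns, got {len(parts)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts
            if feature != "gene":
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_biotype" in attr and "gene_type" not in attr:
                attr["gene_type"] = attr["gene_biotype"]
            missing = [a for a in _MANDATORY_ATTRS if a not in attr]
            if missing:
                raise FormatError(
                    f"{path}:{lineno}: gene line missing attribute(s): {', '.join(missing)}"
                )
            rows.append(
                {
                    "gene_id": attr["gene_id"],
                    "gene_name": attr["gene_name"],
                    "chrom": chrom,
                    "strand": strand,
                    "start": int(start),
                    "end": int(end),
                    "biotype": attr["gene_type"],
                    "status": attr["gene_status"],
                }
            )
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    try:
        return GeneModelSet(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_gtf(genes: GeneModelSet, path: str | Path) -> None:
    """Write gene records as GENCODE-dialect gene feature lines."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in genes.table.itertuples():
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_type "{g.biotype}"; gene_status "{g.status}";'
            )
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# covariates TSV
# ---------------------------------------------------------------------------


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    try:
        return CovariateTable(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cov.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# association results TSV
# ---------------------------------------------------------------------------

RESULT_BASE_COLUMNS = ["chrom", "start", "gene_id", "gene_name", "n_snps", "beta", "se", "p",
                       "significant", "converged"]


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    def key(c: str) -> tuple[int, str]:
        c = str(c).removeprefix("chr")
        return (int(c), "") if c.isdigit() else (10**6, c)

    return chrom.map(key)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a gene association table as TSV, sorted by chromosome then
    gene start position.  An empty table writes a header-only file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = results.copy()
    if len(df):
        df = df.sort_values(
            by=["chrom", "start"], key=lambda s: _chrom_sort_key(s) if s.name == "chrom" else s
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
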