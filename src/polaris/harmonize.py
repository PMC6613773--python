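"""Allele harmonization between target genotypes and external summary stats.

The external effect sizes are defined with respect to a stated effect
allele; the target cohort counts copies of its own a1 allele.  Before the
two can be combined the allele labels must be reconciled:

* identical labels (possibly after complementing the summary-stat alleles
  to the other strand) -> effect size used as-is,
* swapped labels (again possibly after complementing) -> effect size sign
  inverted, so beta always refers to the target's counted allele,
* A/T and C/G (strand-ambiguous) SNPs -> excluded outright, since strand
  cannot be resolved from the labels,
* anything else -> mismatch, excluded.

Matching is by variant id by default; a position mode (chrom:pos plus the
unordered allele pair) is available for id-less data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .io_formats import SummaryStats, VariantRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


class AlleleMatchStatus(Enum):
    MATCH = "match"
    FLIP = "flip"
    STRAND_MATCH = "strand_match"
    STRAND_FLIP = "strand_flip"
    AMBIGUOUS = "ambiguous"
    MISMATCH = "mismatch"


_SIGN = {
    AlleleMatchStatus.MATCH: 1.0,
    AlleleMatchStatus.STRAND_MATCH: 1.0,
    AlleleMatchStatus.FLIP: -1.0,
    AlleleMatchStatus.STRAND_FLIP: -1.0,
}


@dataclass
class HarmonizedWeights:
    """Per-variant effect sizes re-expressed for the target's a1 allele.

    ``table`` columns: id, beta_aligned, status.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        bad = self.table["status"].isin([
            AlleleMatchStatus.AMBIGUOUS.value, AlleleMatchStatus.MISMATCH.value
        ])
        if bad.any():
            raise ValueError("harmonized weights must not contain ambiguous/mismatch variants")
        self.table = self.table.reset_index(drop=True)

    def weight_for(self, variant_id: str) -> float:
        row = self.table[self.table["id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        return float(row["beta_aligned"].iloc[0])

    def __len__(self) -> int:
        return len(self.table)


def classify_allele_pair(
    target_a1: str, target_a2: str, ss_effect: str, ss_other: str
) -> AlleleMatchStatus:
    """Classify one target/summary allele pairing.

    Ambiguity (A/T or C/G target pair) is checked before any matching, so
    ambiguous SNPs are excluded even when the labels agree.
    """
    for a in (target_a1, target_a2, ss_effect, ss_other):
        if a not in _COMPLEMENT:
            raise ValueError(f"non-ACGT allele {a!r}")
    if {target_a1, target_a2} in _AMBIGUOUS or {ss_effect, ss_other} in _AMBIGUOUS:
        return AlleleMatchStatus.AMBIGUOUS
    if (target_a1, target_a2) == (ss_effect, ss_other):
        return AlleleMatchStatus.MATCH
    if (target_a1, target_a2) == (ss_other, ss_effect):
        return AlleleMatchStatus.FLIP
    comp = (_COMPLEMENT[ss_effect], _COMPLEMENT[ss_other])
    if (target_a1, target_a2) == comp:
        return AlleleMatchStatus.STRAND_MATCH
    if (target_a1, target_a2) == (comp[1], comp[0]):
        return AlleleMatchStatus.STRAND_FLIP
    return AlleleMatchStatus.MISMATCH


def _position_key(chrom: str, pos: int, a: str, b: str) -> str:
    return f"{chrom}:{pos}:{':'.join(sorted((a, b)))}"


def harmonize_weights(
    target_variants: list[VariantRecord],
    ss: SummaryStats,
    match_by: str = "id",
    strand_flip: bool = True,
) -> tuple[HarmonizedWeights, dict[str, int]]:
    """Intersect target variants with summary statistics and align betas.

    Returns the kept weights (beta re-signed onto the target's a1 where the
    labels were swapped) and a report counting every drop reason:
    ambiguous, mismatch, unmatched (absent from the summary stats),
    position_conflict (same id, different coordinates) and not_ok
    (summary rows flagged unusable, e.g. monomorphic in discovery).
    Strand-complement rescue applies to non-ambiguous SNPs unless
    ``strand_flip`` is disabled, in which case complement-only matches
    count as mismatches.
    """
    if match_by not in ("id", "position"):
        raise ValueError("match_by must be 'id' or 'position'")
    sst = ss.table
    if match_by == "position":
        keys = {
            _position_key(r.chrom, r.pos, r.effect_allele, r.other_allele): i
            for i, r in enumerate(sst.itertuples())
        }
    else:
        keys = {r.id: i for i, r in enumerate(sst.itertuples())}
    report = {"kept": 0, "ambiguous": 0, "mismatch": 0, "unmatched": 0,
              "position_conflict": 0, "not_ok": 0}
    rows = []
    for v in target_variants:
        key = v.id if match_by == "id" else _position_key(v.chrom, v.pos, v.a1, v.a2)
        idx = keys.get(key)
        if idx is None:
            report["unmatched"] += 1
            continue
        s = sst.iloc[idx]
        if match_by == "id" and (str(s["chrom"]) != v.chrom or int(s["pos"]) != v.pos):
            logger.warning(
                "variant %s maps to %s:%s in target but %s:%s in summary stats; dropped",
                v.id, v.chrom, v.pos, s["chrom"], s["pos"],
            )
            report["position_conflict"] += 1
            continue
        if not bool(s["ok"]):
            report["not_ok"] += 1
            continue
        status = classify_allele_pair(v.a1, v.a2, s["effect_allele"], s["other_allele"])
        if not strand_flip and status in (
            AlleleMatchStatus.STRAND_MATCH, AlleleMatchStatus.STRAND_FLIP
        ):
            status = AlleleMatchStatus.MISMATCH
        if status is AlleleMatchStatus.AMBIGUOUS:
            report["ambiguous"] += 1
            continue
        if status is AlleleMatchStatus.MISMATCH:
            report["mismatch"] += 1
            continue
        rows.append({
            "id": v.id,
            "beta_aligned": _SIGN[status] * float(s["beta"]),
            "status": status.value,
        })
        report["kept"] += 1
    table = pd.DataFrame(rows, columns=["id", "beta_aligned", "status"])
    if table.empty:
        logger.warning("harmonization kept no variants: empty intersection")
    return HarmonizedWeights(table), report


def write_harmonization_report(hw: HarmonizedWeights, report: dict[str, int], path) -> None:
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in report.items():
            fh.write(f"# {k}={v}\n")
    hw.table.to_csv(path, sep="\t", index=False, mode="a")
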