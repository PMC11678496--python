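"""False-positive error alleles in mixtures, typed by pure-sample pair class.

A mixture of DNA1 and DNA2 can only legitimately contain alleles present in
one of the two pure samples. Any base called in a mixture but absent from
both pure samples at that site is a false-positive (FP) error allele. Each
site is classified by what the pure pair carries:

* ``R-R`` — both pure samples are reference-only at the site;
* ``V-V`` — neither pure sample retains the reference base (each is
  homozygous for a variant, VAF >= 0.95);
* ``R-V`` — the pure pair jointly carries both reference and variant bases
  (every other configuration, including a heterozygous DNA2).

R–R sites dominate FP counting in practice: novel alleles there can only be
errors, and the genome-wide universe of such sites is enormous. V–V and R–V
FP counts are computed but secondary.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pairs import HOM_MIN_VAF, NULL_MAX_VAF
from .sensitivity import CutoffCondition
from .vcf_io import CallSet


class PairClass(Enum):
    """Joint allele configuration of DNA1 and DNA2 at a site."""

    R_R = "R-R"
    V_V = "V-V"
    R_V = "R-V"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class FPCounts:
    """FP error allele counts by pair class for one mixture under one condition."""

    rr: int
    vv: int
    rv: int

    @property
    def total(self) -> int:
        return self.rr + self.vv + self.rv

    def by_class(self) -> dict[PairClass, int]:
        return {PairClass.R_R: self.rr, PairClass.V_V: self.vv, PairClass.R_V: self.rv}


def classify_pair_site(
    dna1_alleles: Mapping[str, float], dna2_alleles: Mapping[str, float]
) -> PairClass:
    """Classify a site from each pure sample's alt alleles (alt base -> VAF).

    Only alleles above the null threshold should be passed in; an empty
    mapping means reference-only. A sample "has the reference base" unless
    it is homozygous for a variant (VAF >= 0.95), so V–V requires both
    samples homozygous-variant; any other mixed configuration is R–V.
    """
    if not dna1_alleles and not dna2_alleles:
        return PairClass.R_R
    hom1 = any(v >= HOM_MIN_VAF for v in dna1_alleles.values())
    hom2 = any(v >= HOM_MIN_VAF for v in dna2_alleles.values())
    if hom1 and hom2:
        return PairClass.V_V
    return PairClass.R_V


def _site_alleles(callset: CallSet, null_max: float) -> dict[tuple[str, int], dict[str, float]]:
    """Per autosomal site, alt base -> VAF for alleles above the null threshold."""
    sites: dict[tuple[str, int], dict[str, float]] = {}
    for rec in callset:
        if not rec.key.is_autosomal or rec.vaf <= null_max:
            continue
        sites.setdefault(rec.key.site, {})[rec.key.alt] = rec.vaf
    return sites


def count_fp(
    mixture: CallSet,
    dna1: CallSet,
    dna2: CallSet,
    condition: CutoffCondition,
    null_max: float = NULL_MAX_VAF,
) -> FPCounts:
    """Count FP error alleles in one mixture call set under one condition.

    A mixture record participates when it passes the condition (depth >=
    ``dp_cut`` and VAF >= ``vaf_cut``); its alt base is an FP error iff that
    base is absent from both pure samples at the site — a pure-sample allele
    at or below ``null_max`` does not shield it. The error is tallied under
    the site's :class:`PairClass`. Only mixture calls need enumerating: an
    uncalled allele cannot be a false positive.
    """
    alleles1 = _site_alleles(dna1, null_max)
    alleles2 = _site_alleles(dna2, null_max)
    counts = {PairClass.R_R: 0, PairClass.V_V: 0, PairClass.R_V: 0}
    for rec in mixture:
        if not rec.key.is_autosomal:
            continue
        if rec.vaf <= 0.0 or rec.vaf < condition.vaf_cut or rec.depth < condition.dp_cut:
            continue
        site = rec.key.site
        a1 = alleles1.get(site, {})
        a2 = alleles2.get(site, {})
        if rec.key.alt in a1 or rec.key.alt in a2:
            continue
        counts[classify_pair_site(a1, a2)] += 1
    return FPCounts(rr=counts[PairClass.R_R], vv=counts[PairClass.V_V], rv=counts[PairClass.R_V])


def fp_grid(
    mixtures: Mapping[str, CallSet],
    dna1: CallSet,
    dna2: CallSet,
    dp_cuts: Sequence[int],
    vaf_cuts: Sequence[float],
    null_max: float = NULL_MAX_VAF,
) -> "FPErrorTable":
    """Evaluate :func:`count_fp` over the full cutoff cross for every mixture."""
    if not mixtures:
        raise ValueError("fp_grid requires at least one mixture call set")
    if not dp_cuts or not vaf_cuts:
        raise ValueError("fp_grid requires non-empty cutoff lists")
    records = []
    for sid, callset in mixtures.items():
        for dp_cut in dp_cuts:
            for vaf_cut in vaf_cuts:
                cond = CutoffCondition(dp_cut=dp_cut, vaf_cut=vaf_cut)
                counts = count_fp(callset, dna1, dna2, cond, null_max=null_max)
                for pair_class, n in counts.by_class().items():
                    records.append(
                        {"sample_id": sid, "dp_cut": dp_cut, "vaf_cut": vaf_cut,
                         "pair_class": str(pair_class), "fp_count": n}
                    )
    return FPErrorTable(pd.DataFrame.from_records(records))


class FPErrorTable:
    """Long-format FP counts (sample x condition x class) with per-condition medians."""

    def __init__(self, counts: pd.DataFrame) -> None:
        self.counts = counts

    def class_medians(self) -> pd.DataFrame:
        """Median FP count across mixture samples, per condition and pair class."""
        return (
            self.counts.groupby(["dp_cut", "vaf_cut", "pair_class"], as_index=False)["fp_count"]
            .median()
            .rename(columns={"fp_count": "median_fp"})
        )

    def total_medians(self) -> pd.DataFrame:
        """Median across samples of each sample's total (summed over classes) FP count."""
        totals = (
            self.counts.groupby(["sample_id", "dp_cut", "vaf_cut"], as_index=False)["fp_count"]
            .sum()
        )
        return (
            totals.groupby(["dp_cut", "vaf_cut"], as_index=False)["fp_count"]
            .median()
            .rename(columns={"fp_count": "median_total_fp"})
        )

    def median_total(self, dp_cut: int, vaf_cut: float, pair_class: PairClass | None = None) -> float:
        """Median FP count at one condition: totals by default, one class if given."""
        if pair_class is None:
            df = self.total_medians()
            row = df[(df.dp_cut == dp_cut) & (df.vaf_cut == vaf_cut)]
            return float(row["median_total_fp"].iloc[0])
        df = self.class_medians()
        row = df[
            (df.dp_cut == dp_cut) & (df.vaf_cut == vaf_cut) & (df.pair_class == str(pair_class))
        ]
        return float(row["median_fp"].iloc[0])


def fold_difference(a: float, b: float) -> float:
    """Ratio ``a / b`` rounded half-up to two decimals (e.g. 1844/132 -> 13.97)."""
    if b == 0:
        raise ZeroDivisionError("fold_difference: denominator is zero")
    return float((Decimal(str(a)) / Decimal(str(b))).quantize(Decimal("0.01"), ROUND_HALF_UP))
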