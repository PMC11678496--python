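"""Concordance between two call pipelines and the study's statistics.

Two pipelines run on the same raw data (e.g. a vendor's in-house caller and
a standardized re-analysis) yield two informative-pair sets over the same
DNA1/DNA2 pair. Pairs are matched on (variant key, pair orientation) and
partitioned into *common*, *A-specific* and *B-specific* categories; common
pairs carry each side's own depth/VAF so per-category distributions can be
compared.

Distributional comparisons follow the study's conventions: VAF variability
per eVAF group is summarized by quartiles and the interquartile range
(type-7 linear interpolation); group IQRs of two categories are compared
with the two-sided Wilcoxon matched-pairs signed-rank test pairing groups
of equal eVAF (exact null distribution for small n); read depth and GC
content are compared with the two-sided Mann–Whitney U test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pairs import InformativePair, PairType
from .vcf_io import CallSet, VariantKey

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True)
class CategoryAssignment:
    """Partition of two pair sets into common / A-specific / B-specific."""

    common: frozenset[tuple[VariantKey, PairType]]
    a_only: frozenset[tuple[VariantKey, PairType]]
    b_only: frozenset[tuple[VariantKey, PairType]]

    @property
    def venn(self) -> tuple[int, int, int]:
        """(|A-only|, |common|, |B-only|)."""
        return (len(self.a_only), len(self.common), len(self.b_only))


def categorize_pairs(
    set_a: Sequence[InformativePair], set_b: Sequence[InformativePair]
) -> CategoryAssignment:
    """Match pairs between two sets on (variant key, pair type).

    The pair orientation is part of the match key: an N–Ho pair in one set
    never matches a Ho–N pair at the same variant in the other.
    """
    keys_a = {(p.key, p.pair_type) for p in set_a}
    keys_b = {(p.key, p.pair_type) for p in set_b}
    return CategoryAssignment(
        common=frozenset(keys_a & keys_b),
        a_only=frozenset(keys_a - keys_b),
        b_only=frozenset(keys_b - keys_a),
    )


def split_by_category(
    pairs: Sequence[InformativePair], assignment: CategoryAssignment, side: str
) -> dict[str, list[InformativePair]]:
    """This side's pairs grouped into ``common`` and ``specific`` lists.

    ``side`` is ``"a"`` or ``"b"``; the common pairs keep this side's own
    depth/VAF observations.
    """
    own = assignment.a_only if side == "a" else assignment.b_only
    out: dict[str, list[InformativePair]] = {"common": [], "specific": []}
    for pair in pairs:
        match = (pair.key, pair.pair_type)
        if match in assignment.common:
            out["common"].append(pair)
        elif match in own:
            out["specific"].append(pair)
    return out


def gc_content(reference, key: VariantKey, window_bp: int = 101) -> float | None:
    """GC percentage of a window centered on the variant position.

    ``reference`` is a ``pyfaidx.Fasta`` (or any mapping of contig name to
    sliceable sequence). The window is truncated at contig edges; N bases
    are excluded from the denominator, and an all-N window returns ``None``.
    Contig names are matched with or without a ``chr`` prefix.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    contig = None
    for name in (key.chrom, f"chr{key.chrom}"):
        try:
            contig = reference[name]
            break
        except KeyError:
            continue
    if contig is None:
        raise KeyError(f"chromosome {key.chrom!r} not in reference")
    half = window_bp // 2
    start = max(0, key.pos - 1 - half)
    end = key.pos - 1 + half + 1  # slicing truncates at the contig end
    seq = str(contig[start:end]).upper()
    informative = sum(1 for b in seq if b in "ACGT")
    if informative == 0:
        return None
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / informative


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class QuartileSummary:
    """Q1/median/Q3 and the interquartile range of one group of values."""

    q1: float
    median: float
    q3: float
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def quartiles_iqr(values: Sequence[float]) -> QuartileSummary:
    """Quartiles by linear interpolation between order statistics (type 7)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quartiles_iqr: empty input")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return QuartileSummary(q1=float(q1), median=float(q2), q3=float(q3), n=int(arr.size))


def group_iqrs(pairs: Sequence[InformativePair]) -> pd.DataFrame:
    """Per eVAF group, the quartile summary of observed mixture VAFs."""
    by_group: dict[str, tuple[float, list[float]]] = {}
    for pair in pairs:
        for obs in pair.observations:
            evaf, vals = by_group.setdefault(obs.group_label, (obs.evaf, []))
            vals.append(obs.vaf)
    records = []
    for label, (evaf, vals) in sorted(by_group.items(), key=lambda kv: kv[1][0]):
        summary = quartiles_iqr(vals)
        records.append(
            {"group": label, "evaf": evaf, "n": summary.n, "q1": summary.q1,
             "median": summary.median, "q3": summary.q3, "iqr": summary.iqr}
        )
    return pd.DataFrame.from_records(records)


def adjusted_quartiles(summary: QuartileSummary, center: float = 0.5) -> QuartileSummary:
    """Median-centered quartiles for display: shift so the median sits at ``center``.

    Presentation only — statistics are always computed on raw values.
    """
    shift = center - summary.median
    return QuartileSummary(
        q1=summary.q1 + shift, median=center, q3=summary.q3 + shift, n=summary.n
    )


def wilcoxon_matched(
    iqr_a: Sequence[float], iqr_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon matched-pairs signed-rank test on paired group values.

    Inputs must be paired by identical eVAF group order. Uses the exact null
    distribution for n <= 25 non-zero differences (seven uniformly signed
    pairs give p = 2/2^7 = 0.015625), the normal approximation above, and
    returns (statistic 0, p = 1) when every difference is zero.
    """
    a = np.asarray(iqr_a, dtype=float)
    b = np.asarray(iqr_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 0.0, 1.0
    method = "exact" if nonzero.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    except ValueError:
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method="approx")
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test (exact for small tie-free samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney: empty sample")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def depth_histogram(callset: CallSet) -> pd.DataFrame:
    """Variant count per read depth, with the total read count ``count * depth``."""
    counter = Counter(rec.depth for rec in callset)
    records = [
        {"depth": d, "n_variants": n, "total_reads": n * d} for d, n in sorted(counter.items())
    ]
    return pd.DataFrame.from_records(records, columns=["depth", "n_variants", "total_reads"])
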