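"""Informative null–homozygote allele pairs from a two-genome dilution series.

The reference standard mixes DNA1 — hydatidiform-mole DNA, whose genome is
entirely homozygous — with DNA2, ordinary diploid blood DNA, at known ratios.
A site where one pure sample is reference-only (*null*) and the other is
homozygous for a variant is *informative*: in a mixture with DNA1 fraction
``f1`` the variant must appear at an exactly known expected allele fraction
(eVAF), ``1 - f1`` when the variant lives in DNA2 (an N–Ho pair) and ``f1``
when it lives in DNA1 (a Ho–N pair). Detection of these diluted alleles
across the series is the raw material of the sensitivity analysis.

Selection and trimming thresholds (all boundary-inclusive as stated):

* null means VAF <= 0.05 at the site; homozygous means VAF >= 0.95;
* both pure-sample depths must be >= 10 where assessable;
* a pair is trimmed away when depth < 10 in the mixtures expecting the
  variant nearly undiluted (eVAF >= 0.8), or when the observed mixture VAF
  grossly exceeds expectation (VAF >= 0.7 where eVAF <= 0.2; VAF >= 0.8 at
  eVAF 0.5) — such calls are non-specific, not diluted true variants.

Mixture observations are labelled V5…V95 by ``round(100 * eVAF)``, so the
label order runs opposite to the CH sample order for N–Ho pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import DesignError
from .vcf_io import CallRecord, CallSet, DepthTable, VariantKey

logger = logging.getLogger(__name__)

#: DNA1 (mole) fractions of the canonical CH5…CH95 dilution series.
CANONICAL_FRACTIONS: dict[str, float] = {
    "CH5": 0.05,
    "CH10": 0.10,
    "CH20": 0.20,
    "CH50": 0.50,
    "CH80": 0.80,
    "CH90": 0.90,
    "CH95": 0.95,
}

NULL_MAX_VAF = 0.05
HOM_MIN_VAF = 0.95
DEFAULT_DP_MIN = 10

# Trimming thresholds: mixtures expecting a nearly-undiluted variant must be
# adequately covered; mixtures expecting a dilute variant must not show it
# nearly undiluted.
TRIM_HIGH_EVAF = 0.8  # depth rule applies where eVAF >= this
TRIM_LOW_EVAF = 0.2  # VAF >= 0.7 removal applies where eVAF <= this
TRIM_VAF_LIMIT = 0.7
TRIM_VAF_LIMIT_MID = 0.8  # applies between the two eVAF bands (eVAF 0.5)

_EPS = 1e-9


class PairType(Enum):
    """Orientation of an informative pair: which pure sample carries the variant."""

    N_HO = "N-Ho"  # DNA1 null, DNA2 homozygous variant
    HO_N = "Ho-N"  # DNA1 homozygous variant, DNA2 null

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class MixtureDesign:
    """The dilution series: ordered ``(sample_id, f1)`` with f1 the DNA1 fraction."""

    samples: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise DesignError(f"duplicate sample ids in design: {ids}")
        for sid, f1 in self.samples:
            if not 0.0 < f1 < 1.0:
                raise DesignError(f"mixture {sid}: f1 must be in (0,1), got {f1}")
        fracs = [f1 for _, f1 in self.samples]
        if fracs != sorted(fracs):
            raise DesignError("design samples must be sorted by DNA1 fraction")
        if len(set(fracs)) != len(fracs):
            raise DesignError("DNA1 fractions must be unique")

    @classmethod
    def canonical(cls) -> "MixtureDesign":
        return cls(tuple(sorted(CANONICAL_FRACTIONS.items(), key=lambda kv: kv[1])))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.samples)

    def fraction(self, sample_id: str) -> float:
        for sid, f1 in self.samples:
            if sid == sample_id:
                return f1
        raise DesignError(f"sample {sample_id!r} not in design")


def expected_vaf(pair_type: PairType, f1: float) -> float:
    """Expected allele fraction of an informative variant in a mixture.

    The variant of an N–Ho pair resides in DNA2, so its expected fraction is
    the DNA2 share ``1 - f1``; a Ho–N variant resides in DNA1 and is expected
    at ``f1``.
    """
    if not 0.0 <= f1 <= 1.0:
        raise ValueError(f"f1 must be in [0,1], got {f1}")
    return 1.0 - f1 if pair_type is PairType.N_HO else f1


def group_label(evaf: float) -> str:
    """V-group label for an expected VAF: ``V5`` for 0.05 … ``V95`` for 0.95."""
    return f"V{int(round(100 * evaf))}"


@dataclass(frozen=True)
class MixtureObservation:
    """What one mixture sample shows for one informative pair.

    ``vaf`` is 0 when the allele is absent from the sample's call set (a
    dropped-out variant is the false-negative event being measured, not
    missing data); ``depth`` is then taken from the sample's coverage table,
    or ``None`` when no table covers the site.
    """

    sample_id: str
    depth: int | None
    vaf: float
    evaf: float
    group_label: str


@dataclass(frozen=True)
class InformativePair:
    """One N–Ho or Ho–N pair with its per-mixture observations."""

    key: VariantKey
    pair_type: PairType
    dna1: CallRecord | None
    dna2: CallRecord | None
    dna1_depth: int | None
    dna2_depth: int | None
    observations: tuple[MixtureObservation, ...] = ()

    @property
    def variant_record(self) -> CallRecord | None:
        return self.dna2 if self.pair_type is PairType.N_HO else self.dna1


def _site_max_vaf(callset: CallSet) -> dict[tuple[str, int], float]:
    out: dict[tuple[str, int], float] = {}
    for rec in callset:
        site = rec.key.site
        if rec.vaf > out.get(site, 0.0):
            out[site] = rec.vaf
    return out


def select_nh_pairs(
    dna1: CallSet,
    dna2: CallSet,
    dna1_depths: DepthTable | None = None,
    dna2_depths: DepthTable | None = None,
    dp_min: int = DEFAULT_DP_MIN,
    null_max: float = NULL_MAX_VAF,
    hom_min: float = HOM_MIN_VAF,
    strict: bool = False,
) -> list[InformativePair]:
    """Select informative N–Ho and Ho–N pairs from the two pure call sets.

    An autosomal key makes an N–Ho pair when DNA2 is homozygous for the
    alt (VAF >= ``hom_min``) and DNA1 is null *at the site* — no allele
    there above ``null_max`` (an uncalled site counts as VAF 0) — and both
    depths are >= ``dp_min`` where assessable. Ho–N is the mirror image.

    Depth of the null side comes from that sample's coverage table when the
    site is uncalled. With no table the check is not assessable: the pair is
    retained with a warning in lenient mode (default) and dropped when
    ``strict`` is true. A site homozygous in both samples is not a pair.
    """
    site_max1 = _site_max_vaf(dna1)
    site_max2 = _site_max_vaf(dna2)
    pairs: list[InformativePair] = []
    n_unknown = 0

    # by_site is O(n); hoist out of the per-key loop via _side_depth's caller
    keys = sorted(set(dna1.records) | set(dna2.records))
    by_site1 = dna1.by_site()
    by_site2 = dna2.by_site()

    def side_depth(callset: CallSet, by_site, key: VariantKey, depths) -> int | None:
        rec = callset.get(key)
        if rec is not None:
            return rec.depth
        for other in by_site.get(key.site, []):
            return other.depth
        return depths.get(key.chrom, key.pos) if depths is not None else None

    for key in keys:
        if not key.is_autosomal:
            continue
        rec1 = dna1.get(key)
        rec2 = dna2.get(key)
        vaf1 = rec1.vaf if rec1 is not None else 0.0
        vaf2 = rec2.vaf if rec2 is not None else 0.0
        hom1 = vaf1 >= hom_min
        hom2 = vaf2 >= hom_min
        null1 = site_max1.get(key.site, 0.0) <= null_max
        null2 = site_max2.get(key.site, 0.0) <= null_max

        if hom2 and null1:
            pair_type = PairType.N_HO
        elif hom1 and null2:
            pair_type = PairType.HO_N
        else:
            continue

        d1 = side_depth(dna1, by_site1, key, dna1_depths)
        d2 = side_depth(dna2, by_site2, key, dna2_depths)
        assessable = [d for d in (d1, d2) if d is not None]
        if any(d < dp_min for d in assessable):
            continue
        if len(assessable) < 2:
            n_unknown += 1
            if strict:
                continue
        pairs.append(
            InformativePair(
                key=key, pair_type=pair_type, dna1=rec1, dna2=rec2,
                dna1_depth=d1, dna2_depth=d2,
            )
        )

    if n_unknown:
        logger.warning(
            "%d pair(s) had unknown pure-sample depth (no coverage table); %s",
            n_unknown,
            "dropped (strict mode)" if strict else "retained",
        )
    return pairs


def attach_observations(
    pairs: Iterable[InformativePair],
    mixtures: Mapping[str, CallSet],
    mixture_depths: Mapping[str, DepthTable] | None,
    design: MixtureDesign,
) -> list[InformativePair]:
    """Populate each pair with one labelled observation per design mixture."""
    for sid in design.sample_ids:
        if sid not in mixtures:
            raise DesignError(f"design sample {sid!r} has no call set")
    out = []
    for pair in pairs:
        obs = []
        for sid, f1 in design.samples:
            evaf = expected_vaf(pair.pair_type, f1)
            rec = mixtures[sid].get(pair.key)
            if rec is not None:
                vaf, depth = rec.vaf, rec.depth
            else:
                vaf = 0.0
                table = (mixture_depths or {}).get(sid)
                depth = table.get(pair.key.chrom, pair.key.pos) if table is not None else None
            obs.append(
                MixtureObservation(
                    sample_id=sid, depth=depth, vaf=vaf,
                    evaf=evaf, group_label=group_label(evaf),
                )
            )
        out.append(replace(pair, observations=tuple(obs)))
    return out


def trim_pairs(
    pairs: Sequence[InformativePair],
    mixtures: Mapping[str, CallSet],
    mixture_depths: Mapping[str, DepthTable] | None,
    design: MixtureDesign,
    dp_min: int = DEFAULT_DP_MIN,
    strict: bool = False,
) -> list[InformativePair]:
    """Remove non-specific pairs and label survivors' observations.

    Rules per pair (observations recomputed from ``mixtures``, so applying
    the procedure twice equals applying it once):

    * depth rule — drop when depth < ``dp_min`` in any mixture with
      eVAF >= 0.8 (the variant-carrying pure sample's depth was already
      enforced at selection); unknown depth drops only in strict mode;
    * removal rule — drop when observed VAF >= 0.7 in any mixture with
      eVAF <= 0.2, or VAF >= 0.8 in a mixture with 0.2 < eVAF < 0.8.
    """
    labelled = attach_observations(pairs, mixtures, mixture_depths, design)
    kept: list[InformativePair] = []
    for pair in labelled:
        ok = True
        for obs in pair.observations:
            if obs.evaf >= TRIM_HIGH_EVAF - _EPS:
                if obs.depth is None:
                    if strict:
                        ok = False
                        break
                elif obs.depth < dp_min:
                    ok = False
                    break
            if obs.evaf <= TRIM_LOW_EVAF + _EPS:
                if obs.vaf >= TRIM_VAF_LIMIT:
                    ok = False
                    break
            elif obs.evaf < TRIM_HIGH_EVAF - _EPS:
                if obs.vaf >= TRIM_VAF_LIMIT_MID:
                    ok = False
                    break
        if ok:
            kept.append(pair)
    logger.info("trimmed %d -> %d pairs", len(labelled), len(kept))
    return kept


def write_pairs_tsv(pairs: Sequence[InformativePair], design: MixtureDesign, path) -> None:
    """Export labelled pairs: one row per pair, per-sample depth/vaf/group columns."""
    import csv

    cols = ["chrom", "pos", "ref", "alt", "pair_type"]
    for sid in design.sample_ids:
        cols += [f"{sid}_depth", f"{sid}_vaf", f"{sid}_group"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for pair in pairs:
            row: list = [pair.key.chrom, pair.key.pos, pair.key.ref, pair.key.alt,
                         str(pair.pair_type)]
            by_sid = {o.sample_id: o for o in pair.observations}
            for sid in design.sample_ids:
                o = by_sid[sid]
                row += ["NA" if o.depth is None else o.depth, repr(round(o.vaf, 10)), o.group_label]
            writer.writerow(row)


def read_pairs_tsv(path, design: MixtureDesign) -> list[InformativePair]:
    """Read back the export of :func:`write_pairs_tsv`."""
    import csv

    pairs: list[InformativePair] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = VariantKey(chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"], alt=row["alt"])
            ptype = PairType.N_HO if row["pair_type"] == PairType.N_HO.value else PairType.HO_N
            obs = []
            for sid, f1 in design.samples:
                depth_s = row[f"{sid}_depth"]
                evaf = expected_vaf(ptype, f1)
                obs.append(
                    MixtureObservation(
                        sample_id=sid,
                        depth=None if depth_s == "NA" else int(depth_s),
                        vaf=float(row[f"{sid}_vaf"]),
                        evaf=evaf,
                        group_label=row[f"{sid}_group"],
                    )
                )
            pairs.append(
                InformativePair(key=key, pair_type=ptype, dna1=None, dna2=None,
                                dna1_depth=None, dna2_depth=None, observations=tuple(obs))
            )
    return pairs
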