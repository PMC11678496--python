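"""Reading and normalizing variant call sets and per-base coverage tables.

The evaluation operates on single-nucleotide variants only. Call sets are
normalized on ingest: multi-allelic VCF lines are split into one record per
alternate base, indels/MNVs/symbolic alleles are skipped (and counted), and
chromosome names are stripped of any ``chr`` prefix so that call sets from
differently-styled references can be compared site by site.

VAF (variant allele fraction) is taken from per-allele read counts (the
``AD`` FORMAT field) when present, since the mixture experiments measure
read-level allele fractions; a caller-reported ``AF``/``VAF`` field is used
only as a fallback. A record carrying neither is a fatal error.

Depth at sites *absent* from a sample's VCF (the "null" side of an
informative pair, or a dropped-out mixture call) cannot come from the VCF
itself; an optional :class:`DepthTable` built from a per-base coverage TSV
(``chrom  pos  depth``, the dialect of ``samtools depth``) supplies it.
A lookup of a site the table does not cover returns ``None`` ("unknown"),
never a silent zero.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import DepthTableError, MissingSampleError, VcfError

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: Chromosomes on which informative pairs are selected (autosomes).
AUTOSOMES = frozenset(str(i) for i in range(1, 23))


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr``/``CHR`` prefix from a chromosome name."""
    return chrom[3:] if chrom[:3].lower() == "chr" else chrom


@dataclass(frozen=True, order=True)
class VariantKey:
    """A single-nucleotide variant: chromosome, 1-based position, ref and alt base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases A/C/G/T, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def is_autosomal(self) -> bool:
        return self.chrom in AUTOSOMES


@dataclass(frozen=True)
class CallRecord:
    """One called alternate allele with its total site depth and allele fraction."""

    key: VariantKey
    depth: int
    vaf: float

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0,1], got {self.vaf}")


class CallSet:
    """A sample's normalized SNV calls, keyed by :class:`VariantKey`.

    At most one record per key; multi-allelic input lines are split before
    insertion, so two alternate bases at the same site are two distinct keys.
    """

    def __init__(self, sample_id: str, records: Iterable[CallRecord] = ()) -> None:
        self.sample_id = sample_id
        self.records: dict[VariantKey, CallRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: CallRecord) -> None:
        if record.key in self.records:
            raise VcfError(f"duplicate record for {record.key} in sample {self.sample_id}")
        self.records[record.key] = record

    def get(self, key: VariantKey) -> CallRecord | None:
        return self.records.get(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CallRecord]:
        return iter(self.records.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.records

    def by_site(self) -> dict[tuple[str, int], list[CallRecord]]:
        """Group records by (chrom, pos)."""
        sites: dict[tuple[str, int], list[CallRecord]] = {}
        for rec in self.records.values():
            sites.setdefault(rec.key.site, []).append(rec)
        return sites

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallSet):
            return NotImplemented
        return self.sample_id == other.sample_id and self.records == other.records


class DepthTable:
    """Total read depth per (chrom, pos) for one sample.

    Covers sites regardless of whether a variant was called there. Lookup of
    an uncovered site returns ``None`` — the explicit "unknown" marker — and
    never 0: zero coverage and no information are different statements.
    """

    def __init__(self, depths: Mapping[tuple[str, int], int] | None = None) -> None:
        self._depths: dict[tuple[str, int], int] = {}
        if depths:
            for (chrom, pos), depth in depths.items():
                self.set(chrom, pos, depth)

    def set(self, chrom: str, pos: int, depth: int) -> None:
        chrom = normalize_chrom(chrom)
        if depth < 0:
            raise DepthTableError(f"negative depth {depth} at {chrom}:{pos}")
        if (chrom, pos) in self._depths:
            raise DepthTableError(f"duplicate site {chrom}:{pos} in depth table")
        self._depths[(chrom, pos)] = depth

    def get(self, chrom: str, pos: int) -> int | None:
        return self._depths.get((normalize_chrom(chrom), pos))

    def __len__(self) -> int:
        return len(self._depths)

    def items(self) -> Iterator[tuple[tuple[str, int], int]]:
        return iter(self._depths.items())


def read_depth_table(path: str | Path) -> DepthTable:
    """Read a per-base coverage TSV (``chrom  pos  depth``) into a :class:`DepthTable`.

    A header line starting with ``chrom`` or ``#`` is tolerated. Duplicate
    sites, negative depths and malformed rows are errors.
    """
    path = Path(path)
    if not path.exists():
        raise DepthTableError(f"depth table not found: {path}")
    table = DepthTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1 and (line.startswith("#") or line.split("\t")[0].lower() == "chrom"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DepthTableError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            chrom, pos_s, depth_s = fields[0], fields[1], fields[2]
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise DepthTableError(f"{path}:{lineno}: non-integer pos/depth: {line!r}") from exc
            try:
                table.set(chrom, pos, depth)
            except DepthTableError as exc:
                raise DepthTableError(f"{path}:{lineno}: {exc}") from exc
    return table


def _fmt(value: float) -> str:
    # repr round-trips floats exactly through the text export
    return repr(float(value))


def read_callset(vcf_path: str | Path, sample_id: str, pass_only: bool = False) -> CallSet:
    """Read and normalize one sample's SNV calls from a VCF.

    Parameters
    ----------
    vcf_path
        Plain or bgzipped VCF. May be single- or multi-sample; for a
        multi-sample file ``sample_id`` must name one of its samples.
    sample_id
        Sample to extract, and the id of the returned :class:`CallSet`.
        For a single-sample file whose internal name differs, the single
        sample column is used and relabelled.
    pass_only
        When true, records whose FILTER column is neither PASS nor ``.``
        are skipped. Off by default: filter semantics differ between
        pipelines, and the evaluation applies its own thresholds.

    Notes
    -----
    VAF per alternate allele is ``AD[alt] / sum(AD)`` when the ``AD``
    FORMAT field is present, else a caller-reported per-allele ``AF``/``VAF``
    FORMAT (or INFO ``AF``) field. Depth is FORMAT ``DP`` when present, else
    ``sum(AD)``, else INFO ``DP``. A record offering none of these sources
    for VAF is a fatal :class:`~mixsense.errors.VcfError` naming the line.
    """
    from cyvcf2 import VCF

    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise VcfError(f"VCF not found: {vcf_path}")
    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises plain OSError/Exception on malformed input
        raise VcfError(f"cannot open VCF {vcf_path}: {exc}") from exc

    idx: int | None
    if vcf.samples:
        if sample_id in vcf.samples:
            idx = vcf.samples.index(sample_id)
        elif len(vcf.samples) == 1:
            idx = 0
        else:
            raise MissingSampleError(
                f"sample {sample_id!r} not in {vcf_path} (has {', '.join(vcf.samples)})"
            )
    else:
        idx = None  # sites-only VCF: fall back to INFO fields

    callset = CallSet(sample_id)
    n_skipped = 0
    for var in vcf:
        if pass_only and var.FILTER is not None:
            continue
        chrom = normalize_chrom(var.CHROM)
        ref = var.REF
        alts = var.ALT

        ad = None
        if idx is not None:
            try:
                ad_arr = var.format("AD")
            except KeyError:
                ad_arr = None
            if ad_arr is not None:
                row = ad_arr[idx]
                vals = [int(v) for v in row]
                if any(v >= 0 for v in vals):
                    ad = [max(v, 0) for v in vals]

        dp = None
        if idx is not None:
            try:
                dp_arr = var.format("DP")
            except KeyError:
                dp_arr = None
            if dp_arr is not None and int(dp_arr[idx][0]) >= 0:
                dp = int(dp_arr[idx][0])
        if dp is None:
            info_dp = var.INFO.get("DP")
            if info_dp is not None:
                dp = int(info_dp)

        af_fmt = None
        if ad is None and idx is not None:
            for field in ("AF", "VAF"):
                try:
                    arr = var.format(field)
                except KeyError:
                    arr = None
                if arr is not None:
                    af_fmt = [float(v) for v in arr[idx]]
                    break
        af_info = None
        if ad is None and af_fmt is None:
            raw = var.INFO.get("AF")
            if raw is not None:
                af_info = list(raw) if isinstance(raw, tuple) else [float(raw)]

        for j, alt in enumerate(alts):
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                n_skipped += 1
                continue
            if ad is not None:
                total = sum(ad)
                alt_reads = ad[j + 1] if j + 1 < len(ad) else 0
                vaf = alt_reads / total if total > 0 else 0.0
                depth = dp if dp is not None else total
            elif af_fmt is not None or af_info is not None:
                source = af_fmt if af_fmt is not None else af_info
                try:
                    vaf = float(source[j])
                except (IndexError, TypeError) as exc:
                    raise VcfError(
                        f"{vcf_path}: malformed AF at {var.CHROM}:{var.POS} {ref}>{alt}"
                    ) from exc
                if dp is None:
                    raise VcfError(
                        f"{vcf_path}: no depth (DP/AD) at {var.CHROM}:{var.POS} {ref}>{alt}"
                    )
                depth = dp
            else:
                raise VcfError(
                    f"{vcf_path}: record at {var.CHROM}:{var.POS} {ref}>{alt} has neither "
                    "allele-depth (AD) nor allele-fraction (AF/VAF) information"
                )
            vaf = min(max(vaf, 0.0), 1.0)
            key = VariantKey(chrom=chrom, pos=var.POS, ref=ref, alt=alt)
            callset.add(CallRecord(key=key, depth=depth, vaf=vaf))

    if n_skipped:
        logger.info("%s: skipped %d non-SNV allele(s)", vcf_path.name, n_skipped)
    return callset


TSV_HEADER = ["chrom", "pos", "ref", "alt", "depth", "vaf"]


def write_callset_tsv(callset: CallSet, path: str | Path) -> None:
    """Write a CallSet as TSV with header ``chrom pos ref alt depth vaf``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_HEADER)
        for rec in sorted(callset, key=lambda r: r.key):
            k = rec.key
            writer.writerow([k.chrom, k.pos, k.ref, k.alt, rec.depth, _fmt(rec.vaf)])


def read_callset_tsv(path: str | Path, sample_id: str) -> CallSet:
    """Read a CallSet back from the module's TSV export (round-trip safe)."""
    callset = CallSet(sample_id)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != TSV_HEADER:
            raise VcfError(f"{path}: unexpected header {header}")
        for row in reader:
            chrom, pos, ref, alt, depth, vaf = row
            key = VariantKey(chrom=normalize_chrom(chrom), pos=int(pos), ref=ref, alt=alt)
            callset.add(CallRecord(key=key, depth=int(depth), vaf=float(vaf)))
    return callset
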