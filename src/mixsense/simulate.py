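"""Synthetic reference-standard experiments with known ground truth.

The simulator reproduces the structure the evaluation assumes, at the call
level (no reads): a fully homozygous DNA1 genome mixed with a diploid DNA2
genome at known fractions. Each truth site carries a DNA1 genotype
restricted to {hom-ref, hom-alt} and a DNA2 genotype in {hom-ref, het,
hom-alt}; the expected allele fraction of base ``a`` in a mixture with DNA1
fraction ``f1`` is

    eVAF(a) = f1 * dosage1(a)/2 + (1 - f1) * dosage2(a)/2 .

Per sample and site, total depth is drawn (negative binomial by default,
mimicking exome capture non-uniformity, or fixed for analytic tests), reads
are allocated to alleles multinomially at their expected fractions, and
each read is corrupted with probability ``error_rate`` to a uniformly
chosen other base. A threshold caller (min alt reads / min VAF / min depth)
turns the counts into emitted VCF records, so false negatives arise from
binomial dropout and false positives from injected errors — the two event
classes the evaluation measures.

``analytic_detection`` gives the exact detection probability of a site
under the same model (a finite sum of binomial tails over the depth
distribution), serving as the closed-form oracle for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .errors import DesignError
from .pairs import MixtureDesign
from .vcf_io import CallRecord, CallSet, DepthTable, VariantKey

_BASES = np.array(list("ACGT"))

DNA1_ID = "DNA1"
DNA2_ID = "DNA2"


@dataclass(frozen=True)
class CallerRule:
    """Threshold caller emulation: emit an alt allele when all thresholds pass."""

    min_alt_reads: int = 3
    min_vaf: float = 0.0
    min_depth: int = 0

    def passes(self, alt_reads: int, depth: int) -> bool:
        if depth < self.min_depth or alt_reads < self.min_alt_reads:
            return False
        return depth > 0 and alt_reads / depth >= self.min_vaf


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of a synthetic experiment; the seed is mandatory.

    ``depth_dispersion`` is the negative-binomial size parameter r (variance
    ``m + m^2/r``); the default r = 4 at mean 100 gives a coefficient of
    variation near 0.5, typical of exome capture. ``None`` means fixed depth.
    ``error_rate`` is the per-read substitution probability (split uniformly
    over the three other bases).
    """

    seed: int
    n_contigs: int = 2
    contig_length_bp: int = 50_000
    n_nho_sites: int = 300
    n_hon_sites: int = 300
    n_rr_sites: int = 400
    n_vv_sites: int = 50
    n_rv_sites: int = 100
    depth_mean: float = 100.0
    depth_dispersion: float | None = 4.0
    error_rate: float = 0.001
    caller: CallerRule = field(default_factory=CallerRule)

    def __post_init__(self) -> None:
        if not 1 <= self.n_contigs <= 22:
            raise DesignError("n_contigs must be in 1..22 (autosomal names)")
        for name in ("n_nho_sites", "n_hon_sites", "n_rr_sites", "n_vv_sites", "n_rv_sites"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if not 0.0 <= self.error_rate <= 0.1:
            raise DesignError("error_rate must be in [0, 0.1]")
        if self.depth_mean <= 0:
            raise DesignError("depth_mean must be > 0")

    @property
    def n_sites(self) -> int:
        return (self.n_nho_sites + self.n_hon_sites + self.n_rr_sites
                + self.n_vv_sites + self.n_rv_sites)


@dataclass(frozen=True)
class TruthSite:
    """Ground truth at one position: ref base and both pure-sample genotypes."""

    chrom: str
    pos: int
    ref: str
    dna1_alt: str | None  # DNA1 is hom-alt for this base, or hom-ref when None
    dna2_alt: str | None
    dna2_dosage: int  # 0, 1 or 2 copies of dna2_alt
    category: str  # N-Ho | Ho-N | R-R | V-V | R-V

    def allele_fraction(self, base: str, f1: float) -> float:
        """Expected fraction of ``base`` in a mixture with DNA1 fraction f1."""
        d1 = 2 if self.dna1_alt == base else 0
        d2 = self.dna2_dosage if self.dna2_alt == base else 0
        return f1 * d1 / 2.0 + (1.0 - f1) * d2 / 2.0

    @property
    def alt_bases(self) -> tuple[str, ...]:
        bases = []
        if self.dna1_alt is not None:
            bases.append(self.dna1_alt)
        if self.dna2_alt is not None and self.dna2_alt not in bases:
            bases.append(self.dna2_alt)
        return tuple(bases)


@dataclass(frozen=True)
class TruthSet:
    """All truth sites plus the reference sequences they live on."""

    sites: tuple[TruthSite, ...]
    contigs: Mapping[str, str]
    config: SimulationConfig


@dataclass(frozen=True)
class SimulatedSample:
    sample_id: str
    f1: float  # DNA1 fraction; 1.0 for DNA1, 0.0 for DNA2
    callset: CallSet
    depth_table: DepthTable


@dataclass(frozen=True)
class SimulatedExperiment:
    truth: TruthSet
    design: MixtureDesign
    samples: dict[str, SimulatedSample]

    @property
    def mixtures(self) -> dict[str, CallSet]:
        return {sid: s.callset for sid, s in self.samples.items()
                if sid not in (DNA1_ID, DNA2_ID)}

    @property
    def mixture_depths(self) -> dict[str, DepthTable]:
        return {sid: s.depth_table for sid, s in self.samples.items()
                if sid not in (DNA1_ID, DNA2_ID)}


def _other_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(len(choices))]


def simulate_truth(config: SimulationConfig, rng: np.random.Generator | None = None) -> TruthSet:
    """Draw reference sequences and truth genotypes with exact category counts."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    contigs: dict[str, str] = {}
    positions: list[tuple[str, int]] = []
    per_contig = math.ceil(config.n_sites / config.n_contigs)
    if per_contig > config.contig_length_bp:
        raise DesignError(
            f"{config.n_sites} sites do not fit in {config.n_contigs} "
            f"contig(s) of {config.contig_length_bp} bp"
        )
    remaining = config.n_sites
    for i in range(config.n_contigs):
        name = str(i + 1)
        seq = "".join(rng.choice(_BASES, size=config.contig_length_bp))
        contigs[name] = seq
        take = min(per_contig, remaining)
        pos = rng.choice(config.contig_length_bp, size=take, replace=False) + 1
        positions.extend((name, int(p)) for p in sorted(pos))
        remaining -= take
    categories = (
        ["N-Ho"] * config.n_nho_sites + ["Ho-N"] * config.n_hon_sites
        + ["R-R"] * config.n_rr_sites + ["V-V"] * config.n_vv_sites
        + ["R-V"] * config.n_rv_sites
    )
    rng.shuffle(categories)

    sites = []
    for (chrom, pos), category in zip(positions, categories):
        ref = contigs[chrom][pos - 1]
        dna1_alt: str | None = None
        dna2_alt: str | None = None
        dna2_dosage = 0
        if category == "N-Ho":
            dna2_alt, dna2_dosage = _other_base(rng, ref), 2
        elif category == "Ho-N":
            dna1_alt = _other_base(rng, ref)
        elif category == "V-V":
            dna1_alt = _other_base(rng, ref)
            dna2_alt, dna2_dosage = _other_base(rng, ref), 2
        elif category == "R-V":
            dna2_alt, dna2_dosage = _other_base(rng, ref), 1
        sites.append(
            TruthSite(chrom=chrom, pos=pos, ref=ref, dna1_alt=dna1_alt,
                      dna2_alt=dna2_alt, dna2_dosage=dna2_dosage, category=category)
        )
    return TruthSet(sites=tuple(sites), contigs=contigs, config=config)


def _draw_depth(rng: np.random.Generator, config: SimulationConfig, size: int) -> np.ndarray:
    if config.depth_dispersion is None:
        return np.full(size, int(round(config.depth_mean)), dtype=int)
    r = config.depth_dispersion
    p = r / (r + config.depth_mean)
    return rng.negative_binomial(r, p, size=size)


def _simulate_sample(
    truth: TruthSet, sample_id: str, f1: float, config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulatedSample:
    callset = CallSet(sample_id)
    depth_table = DepthTable()
    eps = config.error_rate
    depths = _draw_depth(rng, config, len(truth.sites))
    base_index = {b: i for i, b in enumerate("ACGT")}
    for site, depth in zip(truth.sites, depths):
        depth = int(depth)
        depth_table.set(site.chrom, site.pos, depth)
        if depth == 0:
            continue
        # true read counts over the four bases
        probs = np.zeros(4)
        alt_frac = 0.0
        for base in site.alt_bases:
            frac = site.allele_fraction(base, f1)
            probs[base_index[base]] += frac
            alt_frac += frac
        probs[base_index[site.ref]] = max(0.0, 1.0 - alt_frac)
        counts = rng.multinomial(depth, probs)
        if eps > 0.0:
            observed = np.zeros(4, dtype=int)
            for i in range(4):
                if counts[i] == 0:
                    continue
                n_err = rng.binomial(counts[i], eps)
                observed[i] += counts[i] - n_err
                if n_err:
                    others = [j for j in range(4) if j != i]
                    observed[others] += rng.multinomial(n_err, [1 / 3] * 3)
            counts = observed
        for i, base in enumerate("ACGT"):
            if base == site.ref or counts[i] == 0:
                continue
            if config.caller.passes(int(counts[i]), depth):
                key = VariantKey(chrom=site.chrom, pos=site.pos, ref=site.ref, alt=base)
                callset.add(CallRecord(key=key, depth=depth, vaf=counts[i] / depth))
    return SimulatedSample(sample_id=sample_id, f1=f1, callset=callset, depth_table=depth_table)


def simulate_mixture_calls(
    truth: TruthSet,
    design: MixtureDesign,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedExperiment:
    """Simulate call sets and coverage for DNA1, DNA2 and every design mixture.

    The pure samples are generated by the same machinery at f1 = 1 and 0.
    Deterministic for a given config seed (or supplied generator).
    """
    config = config if config is not None else truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)  # distinct stream from truth
    samples: dict[str, SimulatedSample] = {}
    plan = [(DNA1_ID, 1.0), (DNA2_ID, 0.0)] + list(design.samples)
    for sample_id, f1 in plan:
        samples[sample_id] = _simulate_sample(truth, sample_id, f1, config, rng)
    return SimulatedExperiment(truth=truth, design=design, samples=samples)


def simulate_experiment(
    config: SimulationConfig, design: MixtureDesign | None = None
) -> SimulatedExperiment:
    """Convenience: truth plus all sample call sets from one config."""
    design = design if design is not None else MixtureDesign.canonical()
    truth = simulate_truth(config)
    return simulate_mixture_calls(truth, design, config)


# ---------------------------------------------------------------------------
# Closed-form oracle


def _alt_read_threshold(rule: CallerRule, depth: int) -> int:
    """Smallest alt-read count the rule accepts at this depth."""
    t = rule.min_alt_reads
    if rule.min_vaf > 0:
        t = max(t, math.ceil(rule.min_vaf * depth - 1e-12))
    return max(t, 1)


def effective_fraction(evaf: float, error_rate: float) -> float:
    """Observed alt-read probability once per-read errors are folded in."""
    return evaf * (1.0 - error_rate) + (1.0 - evaf) * error_rate / 3.0


def analytic_detection(
    evaf: float,
    rule: CallerRule,
    depth: int | None = None,
    config: SimulationConfig | None = None,
    error_rate: float = 0.0,
    tail_mass: float = 1e-9,
) -> float:
    """Exact probability that a site at this eVAF is emitted by the caller.

    Either a fixed ``depth`` or a ``config`` (whose depth distribution is
    marginalized over, truncating the negative-binomial tail at mass
    ``tail_mass``) must be given.
    """
    p = effective_fraction(evaf, error_rate)

    def p_at(d: int) -> float:
        if d < rule.min_depth or d == 0:
            return 0.0
        t = _alt_read_threshold(rule, d)
        return float(stats.binom.sf(t - 1, d, p))

    if depth is not None:
        return p_at(int(depth))
    if config is None:
        raise ValueError("analytic_detection needs a fixed depth or a config")
    if config.depth_dispersion is None:
        return p_at(int(round(config.depth_mean)))
    r = config.depth_dispersion
    q = r / (r + config.depth_mean)
    d_max = int(stats.nbinom.ppf(1 - tail_mass, r, q))
    ds = np.arange(0, d_max + 1)
    weights = stats.nbinom.pmf(ds, r, q)
    return float(sum(w * p_at(int(d)) for d, w in zip(ds, weights) if w > 0))


def analytic_lod(
    rule: CallerRule,
    target: float = 0.95,
    depth: int | None = None,
    config: SimulationConfig | None = None,
    error_rate: float = 0.0,
) -> float:
    """The eVAF at which the analytic detection probability reaches ``target``."""

    def f(evaf: float) -> float:
        return analytic_detection(evaf, rule, depth=depth, config=config,
                                  error_rate=error_rate) - target

    lo, hi = 1e-6, 1.0 - 1e-9
    if f(hi) < 0:
        raise ValueError("caller rule cannot reach the target detection level")
    if f(lo) >= 0:
        return lo
    return float(brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# On-disk realization (VCF 4.2 + coverage TSV + FASTA + truth TSV + manifest)


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (int(chrom), "") if chrom.isdigit() else (99, chrom)


def write_vcf(callset: CallSet, path: str | Path, contigs: Mapping[str, str]) -> None:
    """Write a CallSet as a minimal single-sample VCF 4.2 with GT/AD/DP."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=mixsense-simulate",
    ]
    for name in sorted(contigs, key=_chrom_sort_key):
        lines.append(f"##contig=<ID={name},length={len(contigs[name])}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{callset.sample_id}",
    ]
    for rec in sorted(callset, key=lambda r: (_chrom_sort_key(r.key.chrom), r.key.pos, r.key.alt)):
        alt_reads = int(round(rec.vaf * rec.depth))
        ref_reads = rec.depth - alt_reads
        gt = "1/1" if rec.vaf >= 0.95 else "0/1"
        lines.append(
            f"{rec.key.chrom}\t{rec.key.pos}\t.\t{rec.key.ref}\t{rec.key.alt}\t.\tPASS\t.\t"
            f"GT:AD:DP\t{gt}:{ref_reads},{alt_reads}:{rec.depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_depth_tsv(depth_table: DepthTable, path: str | Path) -> None:
    lines = ["chrom\tpos\tdepth"]
    for (chrom, pos), depth in sorted(
        depth_table.items(), key=lambda kv: (_chrom_sort_key(kv[0][0]), kv[0][1])
    ):
        lines.append(f"{chrom}\t{pos}\t{depth}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(contigs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(contigs, key=_chrom_sort_key):
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_truth_tsv(truth: TruthSet, design: MixtureDesign, path: str | Path) -> None:
    header = ["chrom", "pos", "ref", "category", "dna1_alt", "dna2_alt", "dna2_dosage"]
    header += [f"evaf_{sid}" for sid in design.sample_ids]
    lines = ["\t".join(header)]
    for site in truth.sites:
        row = [site.chrom, str(site.pos), site.ref, site.category,
               site.dna1_alt or ".", site.dna2_alt or ".", str(site.dna2_dosage)]
        for _, f1 in design.samples:
            evaf = max((site.allele_fraction(b, f1) for b in site.alt_bases), default=0.0)
            row.append(f"{evaf:.4f}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_experiment(experiment: SimulatedExperiment, outdir: str | Path) -> Path:
    """Write VCFs, coverage TSVs, FASTA, truth table and an evaluate-ready manifest.

    Returns the manifest path; ``mixsense evaluate --config <manifest>``
    consumes the directory directly.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(experiment.truth.contigs, outdir / "reference.fa")
    write_truth_tsv(experiment.truth, experiment.design, outdir / "truth.tsv")
    manifest: dict = {"samples": [], "seed": experiment.truth.config.seed}
    for sid, sample in experiment.samples.items():
        vcf_path = outdir / f"{sid}.vcf"
        depth_path = outdir / f"{sid}.depth.tsv"
        write_vcf(sample.callset, vcf_path, experiment.truth.contigs)
        write_depth_tsv(sample.depth_table, depth_path)
        entry = {
            "sample_id": sid,
            "vcf": vcf_path.name,
            "depth_table": depth_path.name,
            "role": {DNA1_ID: "dna1", DNA2_ID: "dna2"}.get(sid, "mixture"),
        }
        if entry["role"] == "mixture":
            entry["f1"] = sample.f1
        manifest["samples"].append(entry)
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
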