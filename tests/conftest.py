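import numpy as np
import pytest

from mixsense.pairs import MixtureDesign
from mixsense.vcf_io import CallRecord, CallSet, DepthTable, VariantKey


def make_callset(sample_id, records):
    """Build a CallSet from (chrom, pos, ref, alt, depth, vaf) tuples."""
    cs = CallSet(sample_id)
    for chrom, pos, ref, alt, depth, vaf in records:
        cs.add(CallRecord(key=VariantKey(chrom=str(chrom), pos=pos, ref=ref, alt=alt),
                          depth=depth, vaf=vaf))
    return cs


def make_depth_table(rows):
    """Build a DepthTable from (chrom, pos, depth) tuples."""
    table = DepthTable()
    for chrom, pos, depth in rows:
        table.set(str(chrom), pos, depth)
    return table


@pytest.fixture
def design():
    return MixtureDesign.canonical()


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def random_pure_callsets(rng, n_sites=120, depth=60):
    """Random DNA1/DNA2 call sets plus full coverage tables, for oracle tests.

    Genotype configurations are drawn to exercise every selection branch:
    clean N-Ho/Ho-N pairs, hom/hom conflicts, het sides, borderline VAFs and
    low depths, spread over autosomes plus X to exercise the autosome filter.
    """
    bases = "ACGT"
    chroms = [str(c) for c in list(range(1, 6)) + ["X"]]
    dna1_rows, dna2_rows, d1_depth, d2_depth = [], [], [], []
    used = set()
    for _ in range(n_sites):
        while True:
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(1, 10_000))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        ref = bases[rng.integers(4)]
        alt = rng.choice([b for b in bases if b != ref])
        d1 = int(rng.integers(5, depth))
        d2 = int(rng.integers(5, depth))
        d1_depth.append((chrom, pos, d1))
        d2_depth.append((chrom, pos, d2))
        config = rng.integers(8)
        if config == 0:  # N-Ho candidate
            dna2_rows.append((chrom, pos, ref, alt, d2, float(rng.uniform(0.95, 1.0))))
        elif config == 1:  # Ho-N candidate
            dna1_rows.append((chrom, pos, ref, alt, d1, float(rng.uniform(0.95, 1.0))))
        elif config == 2:  # hom in both (never a pair)
            dna1_rows.append((chrom, pos, ref, alt, d1, 1.0))
            dna2_rows.append((chrom, pos, ref, alt, d2, 1.0))
        elif config == 3:  # het DNA2
            dna2_rows.append((chrom, pos, ref, alt, d2, float(rng.uniform(0.3, 0.7))))
        elif config == 4:  # borderline null vs not-null DNA1, hom DNA2
            dna1_rows.append((chrom, pos, ref, alt, d1, float(rng.choice([0.05, 0.06]))))
            dna2_rows.append((chrom, pos, ref, alt, d2, 1.0))
        elif config == 5:  # borderline hom DNA2
            dna2_rows.append((chrom, pos, ref, alt, d2, float(rng.choice([0.94, 0.95]))))
        # config 6, 7: reference-only in both samples
    return (make_callset("DNA1", dna1_rows), make_callset("DNA2", dna2_rows),
            make_depth_table(d1_depth), make_depth_table(d2_depth))


def random_mixture_callsets(rng, pairs, design, dropout=0.25):
    """Random mixture observations for given pairs: VAF near eVAF, occasional
    dropout, occasional gross outliers to exercise the trimming rules."""
    from mixsense.pairs import expected_vaf

    mixtures, depth_tables = {}, {}
    for sid, f1 in design.samples:
        rows, depths = [], []
        seen = set()
        for pair in pairs:
            key = pair.key
            if key.site in seen:
                continue
            seen.add(key.site)
            depth = int(rng.integers(4, 80))
            depths.append((key.chrom, key.pos, depth))
            if rng.uniform() < dropout:
                continue
            evaf = expected_vaf(pair.pair_type, f1)
            if rng.uniform() < 0.15:
                vaf = float(rng.uniform(0.65, 1.0))  # gross outlier
            else:
                vaf = float(np.clip(evaf + rng.normal(0, 0.05), 0.001, 1.0))
            rows.append((key.chrom, key.pos, key.ref, key.alt, depth, vaf))
        mixtures[sid] = make_callset(sid, rows)
        depth_tables[sid] = make_depth_table(depths)
    return mixtures, depth_tables
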