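"""Brute-force re-implementations used as independent oracles in tests.

These deliberately re-derive every rule from first principles with plain
loops and no shared code with the package, so agreement is meaningful.
"""

AUTOSOMES = {str(i) for i in range(1, 23)}


def oracle_select(dna1, dna2, d1_table, d2_table, dp_min=10):
    """Re-evaluate pair selection per site: returns {(key, 'N-Ho'|'Ho-N')}."""
    out = set()
    all_keys = set(dna1.records) | set(dna2.records)
    for key in all_keys:
        if key.chrom not in AUTOSOMES:
            continue
        r1, r2 = dna1.records.get(key), dna2.records.get(key)
        v1 = r1.vaf if r1 else 0.0
        v2 = r2.vaf if r2 else 0.0
        # null means: nothing above 0.05 anywhere at the site in that sample
        site1 = [r.vaf for r in dna1.records.values() if r.key.site == key.site]
        site2 = [r.vaf for r in dna2.records.values() if r.key.site == key.site]
        null1 = all(v <= 0.05 for v in site1)
        null2 = all(v <= 0.05 for v in site2)
        ptype = None
        if v2 >= 0.95 and null1:
            ptype = "N-Ho"
        elif v1 >= 0.95 and null2:
            ptype = "Ho-N"
        if ptype is None:
            continue
        d1 = r1.depth if r1 else (site_depth(dna1, key) or d1_table.get(key.chrom, key.pos))
        d2 = r2.depth if r2 else (site_depth(dna2, key) or d2_table.get(key.chrom, key.pos))
        if d1 is not None and d1 < dp_min:
            continue
        if d2 is not None and d2 < dp_min:
            continue
        out.add((key, ptype))
    return out


def site_depth(callset, key):
    for rec in callset.records.values():
        if rec.key.site == key.site:
            return rec.depth
    return None


def oracle_trim(selected, mixtures, depth_tables, design, dp_min=10):
    """Re-evaluate the trimming rules for selected {(key, ptype)} pairs."""
    kept = set()
    for key, ptype in selected:
        ok = True
        for sid, f1 in design.samples:
            evaf = (1 - f1) if ptype == "N-Ho" else f1
            rec = mixtures[sid].records.get(key)
            vaf = rec.vaf if rec else 0.0
            if rec is not None:
                depth = rec.depth
            elif depth_tables and sid in depth_tables:
                depth = depth_tables[sid].get(key.chrom, key.pos)
            else:
                depth = None
            if evaf >= 0.8 - 1e-9 and depth is not None and depth < dp_min:
                ok = False
            if evaf <= 0.2 + 1e-9 and vaf >= 0.7:
                ok = False
            if 0.2 + 1e-9 < evaf < 0.8 - 1e-9 and vaf >= 0.8:
                ok = False
        if ok:
            kept.add((key, ptype))
    return kept


def oracle_fp(mixture, dna1, dna2, dp_cut, vaf_cut, null_max=0.05):
    """Re-count FP error alleles by scanning every mixture call directly."""
    counts = {"R-R": 0, "V-V": 0, "R-V": 0}
    for rec in mixture.records.values():
        if rec.key.chrom not in AUTOSOMES:
            continue
        if rec.vaf <= 0 or rec.vaf < vaf_cut or rec.depth < dp_cut:
            continue
        a1 = {r.key.alt: r.vaf for r in dna1.records.values()
              if r.key.site == rec.key.site and r.vaf > null_max}
        a2 = {r.key.alt: r.vaf for r in dna2.records.values()
              if r.key.site == rec.key.site and r.vaf > null_max}
        if rec.key.alt in a1 or rec.key.alt in a2:
            continue
        if not a1 and not a2:
            cls = "R-R"
        elif any(v >= 0.95 for v in a1.values()) and any(v >= 0.95 for v in a2.values()):
            cls = "V-V"
        else:
            cls = "R-V"
        counts[cls] += 1
    return counts


def oracle_categorize(set_a, set_b):
    """Brute-force category partition on (key, pair_type) tuples."""
    ka = {(p.key, p.pair_type) for p in set_a}
    kb = {(p.key, p.pair_type) for p in set_b}
    return ka - kb, ka & kb, kb - ka
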