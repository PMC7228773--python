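"""Independent brute-force re-implementations used as test oracles.

Everything here works one well at a time with plain Python loops and
dicts, deliberately sharing no code with the vectorised implementations
it checks.
"""

from __future__ import annotations

from collections import Counter


def naive_well_counts(wells, min_reads=1):
    tw = vw = 0
    for w in wells:
        if w.ref_reads + w.var_reads >= min_reads:
            tw += 1
        if w.var_reads >= min_reads:
            vw += 1
    return tw, vw


def naive_quality_filter(qf):
    needed = ["QUAL", "FR", "HP", "QD", "SbPval"]
    vals = {}
    for k in needed:
        v = qf.get(k)
        if v is None or v != v:
            return False
        vals[k] = v
    return (vals["QUAL"] > 60 and vals["FR"] > 0.1 and vals["HP"] <= 4
            and vals["QD"] > 10 and vals["SbPval"] <= 0.95)


def naive_well_filter(tw, vw):
    return tw > 5 and vw > 2 and tw > 0 and vw / tw > 0.1


def naive_f20(context21):
    flank = (context21[:10] + context21[11:]).upper()
    counts = Counter(b if b in "ACGT" else "N" for b in flank)
    freqs = sorted((c / 20 for c in counts.values()), reverse=True)
    freqs += [0.0] * (3 - len(freqs))
    return (freqs[0], freqs[0] + freqs[1], freqs[0] + freqs[1] + freqs[2])


GT = {"homref": 0, "het": 1, "homalt": 2, "missing": -1}


def naive_distribution_features(wells, n_rows, n_cols):
    """All 22 plate-distribution features by explicit per-well loops."""
    out = {}
    out["W_ref_novar"] = sum(1 for w in wells if w.ref_reads > 0 and w.var_reads == 0)
    out["W_ref_00"] = sum(1 for w in wells if w.ref_reads > 0 and w.genotype == GT["homref"])
    out["W_ref_01"] = sum(1 for w in wells if w.ref_reads > 0 and w.genotype == GT["het"])
    out["W_var_any"] = sum(1 for w in wells if w.var_reads > 0)
    out["W_var_11"] = sum(1 for w in wells if w.var_reads > 0 and w.genotype == GT["homalt"])
    out["W_var_01"] = sum(1 for w in wells if w.var_reads > 0 and w.genotype == GT["het"])
    out["W_varonly_01"] = sum(1 for w in wells
                              if w.var_reads > 0 and w.ref_reads == 0
                              and w.genotype == GT["het"])
    out["W_refvar_any"] = sum(1 for w in wells if w.ref_reads > 0 and w.var_reads > 0)
    for n in range(6):
        out[f"W_noref_var_gt_{n}"] = sum(
            1 for w in wells if w.ref_reads == 0 and w.var_reads > n)
    var_sorted = sorted((w.var_reads for w in wells), reverse=True)
    rv_sorted = sorted((w.ref_reads + w.var_reads for w in wells), reverse=True)
    for k in (1, 2, 3):
        out[f"Rmax_var_{k}"] = var_sorted[k - 1] if len(var_sorted) >= k else 0
        out[f"Rmax_rv_{k}"] = rv_sorted[k - 1] if len(rv_sorted) >= k else 0
    col_counts = [0] * n_cols
    row_counts = [0] * n_rows
    for w in wells:
        if w.var_reads > 0:
            col_counts[w.col] += 1
            row_counts[w.row] += 1
    out["MaxCR_sum"] = max(col_counts) + max(row_counts)
    out["W_var_minus_MaxCR"] = out["W_var_any"] - out["MaxCR_sum"]
    return out


def naive_rainfall(mutations):
    """(chrom, pos, distance) triples via explicit per-contig grouping."""
    by_chrom = {}
    for chrom, pos, ref, alt in set(mutations):
        by_chrom.setdefault(chrom, []).append((pos, ref, alt))
    out = []
    for chrom in sorted(by_chrom):
        muts = sorted(by_chrom[chrom])
        for prev, cur in zip(muts, muts[1:]):
            out.append((chrom, cur[0], cur[0] - prev[0]))
    return out


def naive_clusters(mutations, max_dist, min_run):
    """Maximal close-spaced runs via a quadratic scan over start points."""
    by_chrom = {}
    for chrom, pos, ref, alt in set(mutations):
        by_chrom.setdefault(chrom, []).append(pos)
    clusters = []
    for chrom in sorted(by_chrom):
        pos = sorted(by_chrom[chrom])
        i = 0
        while i < len(pos):
            j = i
            while j + 1 < len(pos) and pos[j + 1] - pos[j] <= max_dist:
                j += 1
            if j - i + 1 >= min_run:
                clusters.append((chrom, pos[i], pos[j], j - i + 1))
            i = j + 1
    return clusters
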