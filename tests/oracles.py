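"""Independent brute-force evaluators used to cross-check the implementation.

These deliberately use plain Python loops and string operations and share
no code with the package modules they verify.
"""

from __future__ import annotations


def brute_rna_calls(wt_g1, mut_g1, wt_g2, mut_g2, delta=0.5, alpha=0.05, min_base_mean=10.0):
    """Literal evaluation of the two-criterion, both-fraction RNA rule.

    Each table maps feature_id -> (log2fc, base_mean, p_value). Returns
    feature_id -> bool.
    """
    calls = {}
    for fid in wt_g1:
        bm = (wt_g1[fid][1] + mut_g1[fid][1] + wt_g2[fid][1] + mut_g2[fid][1]) / 4.0
        if not bm > min_base_mean:
            calls[fid] = False
            continue
        ok = True
        for wt, mut in ((wt_g1, mut_g1), (wt_g2, mut_g2)):
            lfc_w, _, p_w = wt[fid]
            lfc_m, _, p_m = mut[fid]
            crit_i = (lfc_w - lfc_m) > delta
            wt_sig = lfc_w > 0 and p_w < alpha
            mut_sig = lfc_m > 0 and p_m < alpha
            crit_ii = wt_sig and not mut_sig
            if not (crit_i or crit_ii):
                ok = False
        calls[fid] = ok
    return calls


def brute_protein_calls(values, observed, samples, delta=4.8):
    """Literal evaluation of the two protein routes.

    ``values``: protein -> sample -> imputed log2 value;
    ``observed``: protein -> sample -> bool (pre-imputation);
    ``samples``: list of (sample_id, genotype, fraction, replicate).
    Returns protein -> (called, route).
    """
    def pairs(genotype):
        gran = {r: s for s, g, f, r in samples if g == genotype and f != "tissue_lysate"}
        lys = {r: s for s, g, f, r in samples if g == genotype and f == "tissue_lysate"}
        return [(gran[r], lys[r]) for r in sorted(gran)]

    mut_cols = [s for s, g, _, _ in samples if g == "mutant"]
    out = {}
    for pid in values:
        def lfc(genotype):
            diffs = [values[pid][g] - values[pid][l] for g, l in pairs(genotype)]
            return sum(diffs) / len(diffs)

        mut_absent = all(not observed[pid][s] for s in mut_cols)
        if mut_absent:
            called = lfc("wildtype") > 0
            route = "absent_in_mutant" if called else "none"
        else:
            called = (lfc("wildtype") - lfc("mutant")) >= delta
            route = "delta_ge_4.8" if called else "none"
        out[pid] = (called, route)
    return out


def brute_blacklist(seq, tes, a_fraction=0.70, window=10, tes_protect=250):
    """Per-position A-count scan of one contig; returns strand -> bool list.

    ``tes`` is a list of (position, strand). A position is blacklisted when
    its strand-specific upstream window (read strand) is strictly more than
    ``a_fraction`` A and no same-strand TES lies within ``tes_protect`` bp.
    """
    n = len(seq)
    masks = {"+": [False] * n, "-": [False] * n}
    for pos in range(n):
        for strand in "+-":
            if strand == "+":
                if pos - window < 0:
                    continue
                a_count = seq[pos - window : pos].count("A")
            else:
                if pos + 1 + window > n:
                    continue
                a_count = seq[pos + 1 : pos + 1 + window].count("T")
            if a_count / window > a_fraction:
                protected = any(
                    s == strand and abs(t - pos) <= tes_protect for t, s in tes
                )
                masks[strand][pos] = not protected
    return masks
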