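"""Independent brute-force recomputations used as oracles.

Deliberately written with plain Python loops and the math module (no numpy
vectorisation, no calls into cafscreen internals) so they share no code
path with the implementation they check.
"""

from __future__ import annotations

import math


def pearson(xs, ys):
    """Direct covariance / (sigma * sigma) formula.

    NaN on zero variance; a vector whose spread is indistinguishable from
    rounding noise at its own scale (relative tolerance 1e-12) counts as
    constant, matching the statistic's documented definition.
    """
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sx = math.sqrt(sum((x - mx) ** 2 for x in xs))
    sy = math.sqrt(sum((y - my) ** 2 for y in ys))
    floor_x = 1e-12 * math.sqrt(n) * max(abs(x) for x in xs)
    floor_y = 1e-12 * math.sqrt(n) * max(abs(y) for y in ys)
    if sx <= floor_x or sy <= floor_y:
        return math.nan
    return cov / (sx * sy)


def se_mean_of_paired_ratios(stroma, epithelium):
    ratios = [s / e for s, e in zip(stroma, epithelium) if e != 0]
    if not ratios:
        return math.nan
    return sum(ratios) / len(ratios)


def se_ratio_of_means(stroma, epithelium):
    me = sum(epithelium) / len(epithelium)
    if me == 0:
        return math.nan
    return (sum(stroma) / len(stroma)) / me


def tier(se, se_high=10.0, se_mid=5.0):
    if se is None or math.isnan(se):
        return None
    if se >= se_high:
        return "CAFG"
    if se >= se_mid:
        return "semi_CAFG"
    return "L_CAFG"


def normalized_values(matrix_df, hk_probe):
    """Per-sample division by the housekeeping row, as nested dicts."""
    out = {}
    for probe in matrix_df.index:
        out[probe] = {
            s: matrix_df.at[probe, s] / matrix_df.at[hk_probe, s]
            for s in matrix_df.columns
        }
    return out


def screen_table(matrix_df, hk_probe, stroma, epithelium, anchor, mode,
                 reference_sample=None, se_high=10.0, se_mid=5.0):
    """Probe-by-probe recomputation of the whole screen on a raw matrix.

    Returns {probe: dict} with se_ratio, anchor_r, tier, ref_expression,
    rank_by_expression.
    """
    norm = normalized_values(matrix_df, hk_probe)
    anchor_vec = [norm[anchor][s] for s in stroma]
    rows = {}
    for probe in matrix_df.index:
        svals = [norm[probe][s] for s in stroma]
        evals = [norm[probe][s] for s in epithelium]
        if mode == "mean_of_paired_ratios":
            se = se_mean_of_paired_ratios(svals, evals)
        else:
            se = se_ratio_of_means(svals, evals)
        r = pearson(svals, anchor_vec)
        ref = norm[probe][reference_sample] if reference_sample else math.nan
        rows[probe] = {
            "se_ratio": se,
            "anchor_r": r,
            "tier": tier(se, se_high, se_mid),
            "ref_expression": ref,
        }
    order = sorted(
        rows,
        key=lambda p: (
            -rows[p]["ref_expression"] if not math.isnan(rows[p]["ref_expression"]) else math.inf,
            p,
        ),
    )
    for i, p in enumerate(order, 1):
        rows[p]["rank_by_expression"] = i
    return rows


def count_at_threshold(matrix_df, hk_probe, stroma, anchor, r_min):
    norm = normalized_values(matrix_df, hk_probe)
    anchor_vec = [norm[anchor][s] for s in stroma]
    n = 0
    for probe in matrix_df.index:
        if probe == anchor:
            continue
        r = pearson([norm[probe][s] for s in stroma], anchor_vec)
        if not math.isnan(r) and r >= r_min:
            n += 1
    return n


def overlap(rows, gene_of_probe, mean_stromal, ref_genes, r_min):
    """Best-probe overlap report; rows is the dict from screen_table.

    mean_stromal maps probe -> mean normalized stromal expression, used to
    pick each gene's best probe (ties by probe id).
    """
    by_gene = {}
    for probe, gene in gene_of_probe.items():
        if gene not in by_gene:
            by_gene[gene] = []
        by_gene[gene].append(probe)
    on_chip = sorted(set(by_gene) & set(ref_genes))
    passing = []
    ses = []
    for gene in on_chip:
        best = sorted(by_gene[gene], key=lambda p: (-mean_stromal[p], p))[0]
        r = rows[best]["anchor_r"]
        if not math.isnan(r) and r >= r_min:
            passing.append(gene)
            ses.append(rows[best]["se_ratio"])
    return {
        "n_reference": len(ref_genes),
        "n_on_chip": len(on_chip),
        "n_passing": len(passing),
        "fraction_passing": len(passing) / len(on_chip) if on_chip else math.nan,
        "mean_se_passing": sum(ses) / len(ses) if ses else math.nan,
        "passing_genes": sorted(passing),
    }


def subtype_lists(matrix_df, hk_probe, stroma_all, stroma_subset, anchor,
                  r_subset_min=0.9, r_full_max=0.6):
    norm = normalized_values(matrix_df, hk_probe)
    a_full = [norm[anchor][s] for s in stroma_all]
    a_sub = [norm[anchor][s] for s in stroma_subset]
    shared, specific = [], []
    for probe in matrix_df.index:
        if probe == anchor:
            continue
        r_full = pearson([norm[probe][s] for s in stroma_all], a_full)
        r_sub = pearson([norm[probe][s] for s in stroma_subset], a_sub)
        if math.isnan(r_full) or math.isnan(r_sub):
            continue
        if r_sub >= r_subset_min and r_full >= r_subset_min:
            shared.append(probe)
        if r_sub >= r_subset_min and r_full < r_full_max:
            specific.append(probe)
    return shared, specific
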