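"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops from the textbook definitions,
deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np

MISS = -1


def oracle_maf(dosages) -> float:
    vals = [d for d in dosages if d != MISS]
    p = sum(vals) / (2 * len(vals))
    return min(p, 1 - p)


def oracle_het(dosage: np.ndarray) -> tuple[float, float]:
    """Mean observed/expected heterozygosity over all markers (loops)."""
    hos, hes = [], []
    for j in range(dosage.shape[1]):
        col = [d for d in dosage[:, j] if d != MISS]
        n = len(col)
        hos.append(sum(1 for d in col if d == 1) / n)
        p = sum(col) / (2 * n)
        hes.append(2 * p * (1 - p))
    return float(np.mean(hos)), float(np.mean(hes))


def oracle_proportion_polymorphic(dosage: np.ndarray) -> float:
    poly = 0
    for j in range(dosage.shape[1]):
        col = [d for d in dosage[:, j] if d != MISS]
        p = sum(col) / (2 * len(col))
        if 0 < p < 1:
            poly += 1
    return poly / dosage.shape[1]


def oracle_allelic_richness(dosage: np.ndarray, g: int) -> float:
    vals = []
    for j in range(dosage.shape[1]):
        col = [d for d in dosage[:, j] if d != MISS]
        n_copies = 2 * len(col)
        nb = sum(col)
        na = n_copies - nb
        total = 0.0
        for count in (na, nb):
            drop = (math.comb(n_copies - count, g) / math.comb(n_copies, g)
                    if n_copies - count >= g else 0.0)
            total += 1.0 - drop
        vals.append(total)
    return float(np.mean(vals))


def oracle_common_subset(dosage, group_a, group_b, threshold) -> list[int]:
    keep = []
    for j in range(dosage.shape[1]):
        mafs = []
        for grp in (group_a, group_b):
            col = [dosage[i, j] for i in grp if dosage[i, j] != MISS]
            if not col:
                mafs.append(None)
                continue
            p = sum(col) / (2 * len(col))
            mafs.append(min(p, 1 - p))
        if all(m is not None and m >= threshold for m in mafs):
            keep.append(j)
    return keep


def oracle_ibs(dosage: np.ndarray) -> np.ndarray:
    """Allele-sharing distance by explicit per-locus allele comparison."""
    n = dosage.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ibs1 = ibs2 = total = 0
            for k in range(dosage.shape[1]):
                a, b = dosage[i, k], dosage[j, k]
                if a == MISS or b == MISS:
                    continue
                total += 1
                # genotypes as multisets of alleles {B-count}
                shared = min(a, b) + min(2 - a, 2 - b)
                if shared == 2:
                    ibs2 += 1
                elif shared == 1:
                    ibs1 += 1
            out[i, j] = out[j, i] = 1 - (ibs2 + 0.5 * ibs1) / total
    return out


def oracle_nei(freq_x: np.ndarray, freq_y: np.ndarray) -> float:
    """Nei's standardized distance from allele-b frequency vectors."""
    jxy = jx = jy = 0.0
    for px, py in zip(freq_x, freq_y):
        for ax, ay in ((px, py), (1 - px, 1 - py)):
            jxy += ax * ay
        jx += px ** 2 + (1 - px) ** 2
        jy += py ** 2 + (1 - py) ** 2
    ident = jxy / math.sqrt(jx * jy)
    return math.inf if ident <= 0 else -math.log(min(ident, 1.0))


def oracle_r2(x, y) -> float | None:
    """Textbook squared Pearson correlation over jointly observed samples."""
    pairs = [(a, b) for a, b in zip(x, y) if a != MISS and b != MISS]
    if len(pairs) < 3:
        return None
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
    num = sum((a - mx) * (b - my) for a, b in pairs) ** 2
    den = (sum((a - mx) ** 2 for a in xs) * sum((b - my) ** 2 for b in ys))
    if den == 0:
        return None
    return num / den


def oracle_pair_stream(dosage, positions, chroms, max_bp):
    """All intra-chromosomal (distance, r2) pairs by double loop."""
    out = []
    m = dosage.shape[1]
    for i in range(m):
        for j in range(i + 1, m):
            if chroms[i] != chroms[j]:
                continue
            dist = abs(int(positions[j]) - int(positions[i]))
            if dist == 0 or dist > max_bp:
                continue
            r2 = oracle_r2(dosage[:, i], dosage[:, j])
            if r2 is not None:
                out.append((dist, r2))
    return out


def oracle_bin_means(pairs, width, max_bp):
    """Groupby-style bin means from a (distance, r2) list."""
    n_bins = math.ceil(max_bp / width)
    sums = [[0.0, 0.0, 0] for _ in range(n_bins)]
    for dist, r2 in pairs:
        if dist <= 0 or dist > max_bp:
            continue
        b = math.ceil(dist / width) - 1
        sums[b][0] += r2
        sums[b][1] += dist
        sums[b][2] += 1
    return [
        (k + 1, s / c if c else None, d / c if c else None, c)
        for k, (s, d, c) in enumerate(sums)
    ]


def oracle_fst(dosage: np.ndarray, group_of: list) -> np.ndarray:
    """Per-SNP ANOVA FST on gene copies, fully looped."""
    groups = sorted(set(group_of))
    m = dosage.shape[1]
    out = np.full(m, np.nan)
    for j in range(m):
        copies = {}   # group -> list of 0/1 allele indicators
        for i, g in enumerate(group_of):
            d = dosage[i, j]
            if d == MISS:
                continue
            copies.setdefault(g, []).extend(
                [1] * int(d) + [0] * (2 - int(d)))
        present = [g for g in groups if copies.get(g)]
        r = len(present)
        if r < 2:
            continue
        sizes = {g: len(copies[g]) for g in present}
        n_tot = sum(sizes.values())
        grand = sum(sum(copies[g]) for g in present) / n_tot
        ssb = sum(sizes[g] * (sum(copies[g]) / sizes[g] - grand) ** 2
                  for g in present)
        ssw = sum(sum((a - sum(copies[g]) / sizes[g]) ** 2
                      for a in copies[g]) for g in present)
        msp = ssb / (r - 1)
        msg = ssw / (n_tot - r)
        nc = (n_tot - sum(s ** 2 for s in sizes.values()) / n_tot) / (r - 1)
        denom = msp + (nc - 1) * msg
        out[j] = (msp - msg) / denom if denom != 0 else 0.0
    return out


def oracle_outlier_flags(fst_vals, chroms, positions, quantile):
    """Sort-and-slice top-(1-quantile) flags with the same tie rule."""
    rows = [(v, c, p, k) for k, (v, c, p) in
            enumerate(zip(fst_vals, chroms, positions)) if np.isfinite(v)]
    rows.sort(key=lambda r: (-r[0], r[1], r[2]))
    n_flag = math.floor((1 - quantile) * len(rows))
    return {r[3] for r in rows[:n_flag]}
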