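"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths (and scipy's ranking)
so that agreement is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np

from genofp.keys import PAIR_KEYS, SNV_KEYS


def naive_raw(records, L, C):
    """Quadratic re-implementation of the pair tally: explicit pair listing."""
    by_chrom: dict[str, list] = {}
    order: list[str] = []
    for rec in records:
        if rec.chrom not in by_chrom:
            by_chrom[rec.chrom] = []
            order.append(rec.chrom)
        by_chrom[rec.chrom].append(rec)
    raw = np.zeros((144, L), dtype=np.int64)
    close = np.zeros((144, C), dtype=np.int64)
    for chrom in order:
        recs = by_chrom[chrom]
        for first, second in zip(recs, recs[1:]):
            key = first.ref + first.alt + second.ref + second.alt
            row = PAIR_KEYS.index(key)
            d = second.pos - first.pos - 1
            if d < C:
                close[row][d] += 1
            else:
                raw[row][d % L] += 1
    return raw, close


def average_ranks(values):
    """1-based average ranks with ties, by explicit tie-group iteration."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # mean of 1-based positions i+1..j+1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return np.array(ranks)


def spearman_brute(x, y):
    """Spearman correlation as Pearson correlation of average ranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def random_records(rng, n, n_chroms=4, max_gap=80):
    """Random sorted biallelic SNV stream with distances spanning close/far."""
    from genofp.variants import VariantRecord

    records = []
    for c in range(1, n_chroms + 1):
        m = n // n_chroms + (1 if c <= n % n_chroms else 0)
        if m == 0:
            continue
        gaps = rng.integers(1, max_gap, size=m)
        pos = 1 + np.cumsum(gaps)
        keys = rng.integers(0, 12, size=m)
        for p, k in zip(pos.tolist(), keys.tolist()):
            key = SNV_KEYS[k]
            records.append(VariantRecord(str(c), p, key[0], key[1]))
    return records
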