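"""Independent scalar oracles, coded from the defining formulas only.

Pure-Python loops over ``math`` scalars, deliberately sharing no code path
with the package (no numpy vectorization, no shared softmax helper), so
agreement is evidence of correctness rather than self-consistency.
"""

from __future__ import annotations

import math


def oracle_mse(preds, targets) -> float:
    return sum((p - t) ** 2 for p, t in zip(preds, targets)) / len(preds)


def oracle_per_group_mse(preds, targets, groups) -> dict:
    by_group: dict = {}
    for p, t, g in zip(preds, targets, groups):
        by_group.setdefault(g, []).append((p - t) ** 2)
    return {g: sum(v) / len(v) for g, v in by_group.items()}


def oracle_softmax(values: list[float]) -> list[float]:
    m = max(values)
    exps = [math.exp(v - m) for v in values]
    z = sum(exps)
    return [e / z for e in exps]


def oracle_entropy(p: list[float]) -> float:
    return sum(-x * math.log(x) for x in p if x > 0)


def oracle_moorle_total(preds, targets, groups, a: float) -> float:
    """Direct composition: per-drug MSEs -> softmax -> entropy -> total."""
    group_mse = oracle_per_group_mse(preds, targets, groups)
    mse_values = list(group_mse.values())
    k = len(mse_values)
    mean_mse = sum(mse_values) / k
    if k == 1:
        return mean_mse
    h = oracle_entropy(oracle_softmax(mse_values))
    return mean_mse + a * (math.log(k) - h)


def oracle_r2(y, y_hat) -> float:
    ybar = sum(y) / len(y)
    rss = sum((yi - fi) ** 2 for yi, fi in zip(y, y_hat))
    tss = sum((yi - ybar) ** 2 for yi in y)
    return 1.0 - rss / tss


def oracle_mae(y, y_hat) -> float:
    return sum(abs(yi - fi) for yi, fi in zip(y, y_hat)) / len(y)


def oracle_pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = math.sqrt(sum((a - mx) ** 2 for a in x))
    vy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (vx * vy)


def _ranks(values) -> list[float]:
    """Average ranks (1-based) with tie midpoints."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_spearman(x, y) -> float:
    return oracle_pearson(_ranks(list(x)), _ranks(list(y)))
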