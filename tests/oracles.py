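"""Independent brute-force oracles used to cross-check the package.

Everything here is a direct, slow transliteration of the printed formulas
(explicit Python loops, no shared code with ``ducf``), so the fast
vectorized implementations are checked against an independent path.
"""

from __future__ import annotations

import math

import numpy as np


# -- similarity weights ------------------------------------------------

def pcc_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    den = math.sqrt(sum((x[i] - mx) ** 2 for i in range(n))) * math.sqrt(
        sum((y[i] - my) ** 2 for i in range(n))
    )
    return num / den if den > 0 else float("nan")


def mrc_oracle(x, y):
    mx = float(np.median(list(x)))
    my = float(np.median(list(y)))
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = math.sqrt(sum((xi - mx) ** 2 for xi in x)) * math.sqrt(sum((yi - my) ** 2 for yi in y))
    return num / den if den > 0 else float("nan")


def cos_oracle(x, y):
    num = sum(xi * yi for xi, yi in zip(x, y))
    den = math.sqrt(sum(xi * xi for xi in x)) * math.sqrt(sum(yi * yi for yi in y))
    return num / den if den > 0 else float("nan")


def man_oracle(x, y):
    d = sum(abs(xi - yi) for xi, yi in zip(x, y))
    return float("inf") if d == 0 else 1.0 / d


def euc_oracle(x, y):
    d = math.sqrt(sum((xi - yi) ** 2 for xi, yi in zip(x, y)))
    return float("inf") if d == 0 else 1.0 / d


SIMILARITY_ORACLES = {
    "pcc": pcc_oracle,
    "mrc": mrc_oracle,
    "cos": cos_oracle,
    "man": man_oracle,
    "euc": euc_oracle,
}


# -- performance metrics ----------------------------------------------

def mae_oracle(x, y):
    return sum(abs(yi - xi) for xi, yi in zip(x, y)) / len(x)


def mse_oracle(x, y):
    return sum((yi - xi) ** 2 for xi, yi in zip(x, y)) / len(x)


def rmse_oracle(x, y):
    return math.sqrt(mse_oracle(x, y))


def rsq_oracle(x, y):
    xbar = sum(x) / len(x)
    den = sum((xbar - xi) ** 2 for xi in x)
    num = sum((yi - xi) ** 2 for xi, yi in zip(x, y))
    return 1.0 - num / den if den > 0 else float("nan")


# -- full imputer ------------------------------------------------------

def bruteforce_impute(
    values: np.ndarray,
    mask: np.ndarray,
    score_cols: dict[str, int],
    form_cols: list[int],
    measure: str,
    bnc: int,
    sample_ids: list,
    min_overlap: int = 2,
) -> dict[tuple[object, str], float]:
    """Enumerate-sort-average reference imputer for tiny cohorts.

    For each missing score cell: pairwise-complete similarity of the
    target to every other sample over ``form_cols`` minus the score
    column, infinite sentinels replaced by the matrix-wide finite maximum,
    candidates restricted to samples with the score observed, sorted by
    (weight desc, sample id asc), truncated to ``bnc``, then the signed
    weighted average (unweighted mean when the weight sum is ~0).
    """
    fn = SIMILARITY_ORACLES[measure]
    n = values.shape[0]
    out: dict[tuple[object, str], float] = {}
    for score, cs in score_cols.items():
        cols = [j for j in form_cols if j != cs]
        # full similarity matrix with pairwise-complete vectors
        W = [[float("nan")] * n for _ in range(n)]
        for a in range(n):
            for b in range(n):
                if a == b:
                    continue
                xs, ys = [], []
                for j in cols:
                    if mask[a, j] and mask[b, j]:
                        xs.append(values[a, j])
                        ys.append(values[b, j])
                if len(xs) < max(1, min_overlap):
                    continue
                W[a][b] = fn(xs, ys)
        finite = [w for row in W for w in row if not math.isnan(w) and not math.isinf(w)]
        if measure in ("man", "euc"):
            top = max(finite) if finite else None
            for a in range(n):
                for b in range(n):
                    if math.isinf(W[a][b]):
                        if top is None:
                            raise ValueError("degenerate cohort")
                        W[a][b] = top
        for t in range(n):
            if mask[t, cs]:
                continue
            cands = [
                (W[t][b], b)
                for b in range(n)
                if b != t and mask[b, cs] and not math.isnan(W[t][b])
            ]
            if not cands:
                out[(sample_ids[t], score)] = float("nan")
                continue
            cands.sort(key=lambda wb: (-wb[0], str(sample_ids[wb[1]])))
            chosen = cands[:bnc]
            wsum = sum(w for w, _ in chosen)
            if abs(wsum) < 1e-12:
                pred = sum(values[b, cs] for _, b in chosen) / len(chosen)
            else:
                pred = sum(values[b, cs] * w for w, b in chosen) / wsum
            out[(sample_ids[t], score)] = pred
    return out
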