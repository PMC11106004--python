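"""Rank-based statistics used throughout the community analysis.

Spearman correlation, Kruskal-Wallis with tie correction, Dunn's post-hoc
z-tests, the Hellinger transform, and ANOSIM are implemented at the formula
level with midranks everywhere.  Distribution lookups (t, chi-square,
normal) come from scipy; everything else is explicit so the tie handling
and permutation conventions are pinned down.
"""

from __future__ import annotations

from itertools import combinations, permutations
from typing import Optional

import numpy as np
from scipy import stats as sps

__all__ = [
    "spearman",
    "kruskal_wallis",
    "dunn_posthoc",
    "hellinger",
    "anosim",
]


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of midranks.  For n >= 10 the p-value
    uses the t approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees
    of freedom; for n < 10 it is exact, by enumerating all n! permutations
    of one variable's ranks and counting |rho| at least as large as
    observed.

    Raises ``ValueError`` on constant input (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    rx = _midranks(x)
    ry = _midranks(y)
    sx = rx.std(ddof=0)
    sy = ry.std(ddof=0)
    if sx == 0 or sy == 0:
        raise ValueError("rho undefined for constant input")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))

    if n >= 10:
        if abs(rho) == 1.0:
            return rho, 0.0
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        return rho, min(1.0, p)

    # Exact permutation null.  rho is a monotone function of the rank dot
    # product, but midrank ties make the mapping affine with the same slope
    # for every permutation of ry, so comparing |rho| directly is exact.
    obs = abs(rho)
    count = 0
    total = 0
    denom = n * sx * sy
    mx, my = rx.mean(), ry.mean()
    for perm in permutations(ry):
        rp = np.array(perm)
        r = np.sum((rx - mx) * (rp - my)) / denom
        if abs(r) >= obs - 1e-12:
            count += 1
        total += 1
    return rho, count / total


def _check_groups(values, labels) -> tuple[np.ndarray, list, list[np.ndarray]]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    masks = [labels == g for g in uniq]
    for g, m in zip(uniq, masks):
        if m.sum() == 0:
            raise ValueError(f"group {g} is empty")
    return values, uniq, masks


def _tie_sum(ranked: np.ndarray) -> float:
    _, counts = np.unique(ranked, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Kruskal-Wallis H test with tie correction.

    H = 12/(N(N+1)) * sum_i n_i (Rbar_i - Rbar)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N).  The p-value comes from the
    chi-square distribution with k-1 degrees of freedom.  When every value
    is identical the statistic is 0 and p = 1 by convention.
    """
    values, uniq, masks = _check_groups(values, labels)
    n = len(values)
    if n < 3:
        raise ValueError("need total n >= 3")
    ranks = _midranks(values)
    rbar = (n + 1) / 2.0
    h = 0.0
    for m in masks:
        ni = m.sum()
        h += ni * (ranks[m].mean() - rbar) ** 2
    h *= 12.0 / (n * (n + 1))
    correction = 1.0 - _tie_sum(values) / (n**3 - n)
    if correction <= 0:  # all values tied
        return 0.0, 1.0
    h /= correction
    p = float(sps.chi2.sf(h, df=len(uniq) - 1))
    return float(h), p


def dunn_posthoc(values, labels, adjust: str = "holm") -> list[dict]:
    """Dunn's post-hoc pairwise z-tests following Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - sum(t^3-t)/(12(N-1)))
    * (1/n_i + 1/n_j)] with midranks shared across all groups.  The sign
    follows the order in which group labels first appear.  Two-sided normal
    p-values, adjusted by ``holm`` (default), ``bonferroni`` or ``none``.

    Returns one dict per pair: group_a, group_b, z, p_raw, p_adjusted.
    """
    if adjust not in ("none", "holm", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    values, uniq, masks = _check_groups(values, labels)
    n = len(values)
    ranks = _midranks(values)
    tie_term = _tie_sum(values) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    results = []
    for (ga, ma), (gb, mb) in combinations(zip(uniq, masks), 2):
        na, nb = ma.sum(), mb.sum()
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = 0.0 if se == 0 else float((ranks[ma].mean() - ranks[mb].mean()) / se)
        p = float(2.0 * sps.norm.sf(abs(z)))
        results.append({"group_a": ga, "group_b": gb, "z": z, "p_raw": min(1.0, p)})
    m = len(results)
    if adjust == "none":
        for r in results:
            r["p_adjusted"] = r["p_raw"]
    elif adjust == "bonferroni":
        for r in results:
            r["p_adjusted"] = min(1.0, r["p_raw"] * m)
    else:  # holm step-down
        order = np.argsort([r["p_raw"] for r in results], kind="stable")
        running = 0.0
        for rank_i, idx in enumerate(order.tolist()):
            padj = (m - rank_i) * results[idx]["p_raw"]
            running = max(running, min(1.0, padj))
            results[idx]["p_adjusted"] = running
    return results


def hellinger(counts) -> np.ndarray:
    """Hellinger transform: sqrt of per-row relative abundances.

    Accepts a 1-D count vector or a 2-D samples-by-taxa matrix.  Euclidean
    distance between transformed rows equals the Hellinger distance between
    the original composition vectors.  A zero row sum is an error.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    one_d = counts.ndim == 1
    mat = counts[None, :] if one_d else counts
    sums = mat.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("every row must have a positive sum")
    out = np.sqrt(mat / sums)
    return out[0] if one_d else out


def _anosim_r(ranked: np.ndarray, within: np.ndarray) -> float:
    m = len(ranked)
    r_w = ranked[within].mean()
    r_b = ranked[~within].mean()
    return float((r_b - r_w) / (m / 2.0))


def anosim(
    distances,
    labels,
    n_perm: int = 9999,
    seed: Optional[int] = 0,
) -> tuple[float, float]:
    """Analysis of similarities on a symmetric distance matrix.

    All M = n(n-1)/2 pairwise distances are midranked; with r_B and r_W the
    mean ranks of between- and within-group pairs,

        R = (r_B - r_W) / (M / 2),  R in [-1, 1].

    The p-value is (1 + #{permuted R >= observed}) / (1 + n_perm) over
    seeded random label permutations.  Every group needs >= 2 members.
    """
    d = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distances must be a symmetric matrix with zero diagonal")
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs >= 2 members")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    iu = np.triu_indices(n, k=1)
    ranked = _midranks(d[iu])
    within = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranked, within)

    rng = np.random.default_rng(seed)
    count = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        w = lab[iu[0]] == lab[iu[1]]
        if _anosim_r(ranked, w) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p
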