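"""Independent brute-force reference implementations used only by the tests.

Everything here is deliberately naive (loops, enumeration, exact integer
arithmetic) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up by direct application of the definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        j = rank_from_top + 1
        running_min = min(running_min, p[order[rank_from_top]] * m / j)
        q_sorted[rank_from_top] = running_min
    q = np.empty(m)
    q[order] = q_sorted
    return q


def wilcoxon_exact_two_sided(x, y) -> float:
    """Two-sided rank-sum p by enumerating all rank configurations (tie-free)."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires tie-free data"
    n, m = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    us = []
    for positions in combinations(range(1, n + m + 1), n):
        us.append(sum(positions) - n * (n + 1) / 2)
    us = np.asarray(us)
    p_ge = np.mean(us >= u_obs)
    p_le = np.mean(us <= u_obs)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def wilcoxon_exact_dp(x, y) -> float:
    """Exact two-sided rank-sum p via the subset-sum counting recursion.

    Counts, for tie-free pooled data, how many of the C(n+m, n) rank subsets
    give each rank-sum; feasible for group sizes well beyond direct
    enumeration.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled)
    n, m = len(x), len(y)
    N = n + m
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    max_sum = N * (N + 1) // 2
    # counts[k][s] = number of k-subsets of ranks seen so far with sum s
    counts = [[0] * (max_sum + 1) for _ in range(n + 1)]
    counts[0][0] = 1
    for r in range(1, N + 1):
        for k in range(min(r, n), 0, -1):
            row_k, row_km1 = counts[k], counts[k - 1]
            for s in range(max_sum, r - 1, -1):
                row_k[s] += row_km1[s - r]
    dist = counts[n]
    total = math.comb(N, n)
    p_ge = sum(dist[s] for s in range(w_obs, max_sum + 1)) / total
    p_le = sum(dist[s] for s in range(0, w_obs + 1)) / total
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def fisher_exact_two_sided(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Works in exact integer arithmetic on the unnormalized pmf; a term enters
    the sum when its pmf does not exceed the observed one beyond floating
    round-off (relative 1e-7, matching the usual two-sided convention).
    """
    k = k1 + k2
    denom = math.comb(n1 + n2, k)
    obs = math.comb(n1, k1) * math.comb(n2, k2)
    total = 0
    for x in range(max(0, k - n2), min(n1, k) + 1):
        term = math.comb(n1, x) * math.comb(n2, k - x)
        if term <= obs or (term - obs) <= obs * 1e-7:
            total += term
    return min(1.0, total / denom)


def rank_average(values: np.ndarray) -> np.ndarray:
    """Average ranks computed by explicit tie grouping."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman_by_hand(a, b) -> float:
    ra, rb = rank_average(np.asarray(a, float)), rank_average(np.asarray(b, float))
    ra -= ra.mean()
    rb -= rb.mean()
    denom = math.sqrt((ra**2).sum() * (rb**2).sum())
    if denom == 0:
        return float("nan")
    return float((ra * rb).sum() / denom)


def normal_upper_tail(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def naive_lr_reference(
    norm,
    candidates: pd.DataFrame,
    *,
    n_permutations: int,
    seed: int,
    epsilon: float = 1e-9,
    case: str = "case",
    control: str = "control",
) -> pd.DataFrame:
    """Loop-based reference for the interaction-potential permutation test.

    Reproduces the published shuffling protocol (one relabeling per replicate,
    subtypes in sorted order, one RNG permutation each — the protocol is part
    of the statistic's definition) but computes every potential, ratio,
    standardized ratio, p and q with independent naive loops.
    """
    X = np.asarray(norm.X)
    genes = list(norm.var_names)
    gidx = {g: i for i, g in enumerate(genes)}
    tvec = norm.obs["cell_type"].to_numpy()
    svec = norm.obs["cell_subtype"].to_numpy()
    cond = norm.obs["condition"].to_numpy()

    def potential(cvec, sender, receiver, ligand, receptor, label):
        s_rows = [i for i in range(len(cvec)) if tvec[i] == sender and cvec[i] == label]
        r_rows = [i for i in range(len(cvec)) if tvec[i] == receiver and cvec[i] == label]
        lig = sum(X[i, gidx[ligand]] for i in s_rows) / len(s_rows)
        rec = sum(X[i, gidx[receptor]] for i in r_rows) / len(r_rows)
        return lig * rec

    def ratio_for(cvec, row):
        pc = potential(cvec, row.sender, row.receiver, row.ligand, row.receptor, case)
        pn = potential(cvec, row.sender, row.receiver, row.ligand, row.receptor, control)
        return (pc + epsilon) / (pn + epsilon), pc, pn

    real = [ratio_for(cond, row) for row in candidates.itertuples(index=False)]

    cond01 = np.where(cond == case, 1, 0).astype(np.int8)
    rng = np.random.default_rng(seed)
    rand = np.empty((n_permutations, len(candidates)))
    label_of = {1: case, 0: control}
    for rep in range(n_permutations):
        cperm01 = cond01.copy()
        for s in sorted(set(svec)):
            block = np.flatnonzero(svec == s)
            cperm01[block] = rng.permutation(cond01[block])
        cperm = np.array([label_of[c] for c in cperm01])
        for j, row in enumerate(candidates.itertuples(index=False)):
            rand[rep, j] = ratio_for(cperm, row)[0]

    rows = []
    for j, row in enumerate(candidates.itertuples(index=False)):
        r, pc, pn = real[j]
        mu = rand[:, j].mean()
        sd = rand[:, j].std(ddof=1)
        if sd == 0:
            z = math.inf if r > mu else (-math.inf if r < mu else 0.0)
            p = 0.0 if r > mu else (1.0 if r < mu else 0.5)
        else:
            z = (r - mu) / sd
            p = normal_upper_tail(z)
        rows.append((row.sender, row.receiver, row.ligand, row.receptor, pc, pn, r, z, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "sender", "receiver", "ligand", "receptor",
            "potential_case", "potential_control", "ratio", "z", "p",
        ],
    )
    out["q"] = bh_stepup(out["p"].to_numpy())
    return out
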