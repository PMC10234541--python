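"""Ligand-receptor interaction potentials with a condition-label permutation null.

For a sender cell type A, receiver cell type B, ligand L and receptor R, the
interaction potential of a condition is

    potential = mean(L over A-cells of the condition)
              * mean(R over B-cells of the condition)

on sum-normalized expression. The case/control contrast is the ratio of the
two potentials (a tiny epsilon keeps zero control potentials finite). Its
null distribution comes from re-assigning cells to the two conditions at
random *within each cell subtype* — preserving every subtype's case/control
counts — and recomputing the ratio; with ``n_permutations`` such relabelings
the standardized ratio is

    z = (ratio - mean(randomized ratios)) / sd(randomized ratios)

and the one-sided p-value is the upper normal tail, Phi-complement of z
("probability that the observed ratio is higher than expected by chance").
Q-values are Benjamini-Hochberg over all candidates of the run.

Protocol details that pin determinism: one relabeling per replicate shared by
all candidates, subtypes processed in sorted order with one RNG permutation
each, and the randomized-ratio standard deviation uses ddof=1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import norm as normal

from .dge import benjamini_hochberg

__all__ = [
    "LRParams",
    "candidate_interactions",
    "interaction_potential",
    "permutation_test",
    "top_interactions",
]

logger = logging.getLogger(__name__)


@dataclass
class LRParams:
    n_permutations: int = 100
    min_cells_expressing: int = 10
    min_fraction_expressing: float = 0.10
    q_threshold: float = 0.01
    top_k: int = 25
    epsilon: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 2:
            raise ValueError("n_permutations must be >= 2 for a defined sd")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _expression_ok(
    X: np.ndarray, cells_of: dict[tuple[str, str], np.ndarray],
    cell_type: str, conditions: tuple[str, str], gene_col: int, params: LRParams,
) -> bool:
    """True when the gene is expressed in >=min cells AND >=min fraction of the
    type's cells within at least one condition."""
    for cond in conditions:
        idx = cells_of.get((cell_type, cond))
        if idx is None or idx.size == 0:
            continue
        n_expr = int((X[idx, gene_col] > 0).sum())
        if n_expr >= params.min_cells_expressing and n_expr / idx.size >= params.min_fraction_expressing:
            return True
    return False


def candidate_interactions(
    norm: ad.AnnData,
    pairs: pd.DataFrame,
    params: LRParams | None = None,
    *,
    type_key: str = "cell_type",
    condition_key: str = "condition",
    case: str = "case",
    control: str = "control",
) -> pd.DataFrame:
    """Expression-filtered (sender, receiver, ligand, receptor) candidates.

    All ordered sender-receiver type pairs are considered (self-pairs
    included). A pair qualifies when the ligand passes the 10-cell/10% rule in
    the sender type and the receptor passes it in the receiver type, each
    within at least one condition. Pairs whose ligand or receptor is absent
    from the gene universe are skipped.
    """
    params = params or LRParams()
    if pairs.empty:
        raise ValueError("ligand-receptor pair table is empty")
    gene_idx = {g: i for i, g in enumerate(norm.var_names)}
    X = np.asarray(norm.X)
    types = sorted(pd.unique(norm.obs[type_key]))
    conds = norm.obs[condition_key].to_numpy()
    tvec = norm.obs[type_key].to_numpy()
    cells_of = {
        (t, c): np.flatnonzero((tvec == t) & (conds == c))
        for t in types
        for c in (case, control)
    }
    rows = []
    for ligand, receptor in pairs[["ligand", "receptor"]].itertuples(index=False):
        if ligand not in gene_idx or receptor not in gene_idx:
            logger.warning("pair (%s, %s) not in gene universe, skipped", ligand, receptor)
            continue
        li, ri = gene_idx[ligand], gene_idx[receptor]
        senders = [
            t for t in types
            if _expression_ok(X, cells_of, t, (case, control), li, params)
        ]
        receivers = [
            t for t in types
            if _expression_ok(X, cells_of, t, (case, control), ri, params)
        ]
        for s in senders:
            for r in receivers:
                rows.append((s, r, ligand, receptor))
    return pd.DataFrame(rows, columns=["sender", "receiver", "ligand", "receptor"])


def interaction_potential(
    norm: ad.AnnData,
    sender: str,
    receiver: str,
    ligand: str,
    receptor: str,
    condition: str,
    *,
    type_key: str = "cell_type",
    condition_key: str = "condition",
) -> float:
    """Mean ligand expression in sender cells x mean receptor expression in receivers."""
    tvec = norm.obs[type_key].to_numpy()
    conds = norm.obs[condition_key].to_numpy()
    s_idx = np.flatnonzero((tvec == sender) & (conds == condition))
    r_idx = np.flatnonzero((tvec == receiver) & (conds == condition))
    if s_idx.size == 0 or r_idx.size == 0:
        raise ValueError(
            f"empty group: {sender}/{receiver} in condition {condition!r}"
        )
    lig = float(np.asarray(norm[s_idx, ligand].X).mean())
    rec = float(np.asarray(norm[r_idx, receptor].X).mean())
    return lig * rec


def _subtype_blocks(subtypes: np.ndarray) -> list[np.ndarray]:
    """Cell index blocks per subtype, in sorted subtype order (the shuffle unit)."""
    return [np.flatnonzero(subtypes == s) for s in sorted(pd.unique(subtypes))]


def permutation_test(
    norm: ad.AnnData,
    candidates: pd.DataFrame,
    params: LRParams | None = None,
    *,
    type_key: str = "cell_type",
    subtype_key: str = "cell_subtype",
    condition_key: str = "condition",
    case: str = "case",
    control: str = "control",
    direction: str = "case-over-control",
    return_null: bool = False,
) -> pd.DataFrame:
    """Standardized-ratio permutation test over a candidate list.

    Returns one record per candidate with columns sender, receiver, ligand,
    receptor, potential_case, potential_control, ratio, z, p, q and a
    ``degenerate`` flag for zero-sd nulls (where p falls back to the limit of
    the normal tail: 0.5 if the observed ratio equals the common randomized
    value, 0 if above, 1 if below). Deterministic given ``params.seed``.

    With ``return_null=True`` also returns the randomized-ratio matrix
    (replicates x candidates) for calibration diagnostics against the
    empirical permutation tail.
    """
    params = params or LRParams()
    if candidates.empty:
        raise ValueError("candidate list is empty")
    if direction not in ("case-over-control", "control-over-case"):
        raise ValueError(f"unknown direction {direction!r}")

    genes_needed = sorted(set(candidates["ligand"]) | set(candidates["receptor"]))
    gene_col = {g: j for j, g in enumerate(genes_needed)}
    X = np.asarray(norm[:, genes_needed].X)
    tvec = norm.obs[type_key].to_numpy()
    subtypes = norm.obs[subtype_key].to_numpy()
    conds_raw = norm.obs[condition_key].to_numpy()
    cond = np.where(conds_raw == case, 1, 0).astype(np.int8)
    if not ((conds_raw == case) | (conds_raw == control)).all():
        raise ValueError("cells with conditions outside {case, control} present")

    types = sorted(pd.unique(tvec))
    type_code = {t: k for k, t in enumerate(types)}
    needed_types = set(candidates["sender"]) | set(candidates["receiver"])
    for t in needed_types:
        if t not in type_code:
            raise ValueError(f"candidate references unknown cell type {t!r}")
        for c, lab in ((1, case), (0, control)):
            if not ((tvec == t) & (cond == c)).any():
                raise ValueError(f"cell type {t!r} has no {lab!r} cells")

    # per-type slices; group means are recomputed from a 0/1 condition vector
    type_rows = {t: np.flatnonzero(tvec == t) for t in types}
    X_t = {t: X[idx] for t, idx in type_rows.items()}

    def group_means(cvec: np.ndarray) -> np.ndarray:
        """means[type, cond, gene] for the given 0/1 condition assignment."""
        out = np.empty((len(types), 2, X.shape[1]))
        for t, rows in type_rows.items():
            c_local = cvec[rows]
            k = type_code[t]
            for c in (0, 1):
                mask = c_local == c
                n = int(mask.sum())
                out[k, c] = X_t[t][mask].sum(axis=0) / n if n else np.nan
        return out

    send_k = candidates["sender"].map(type_code).to_numpy()
    recv_k = candidates["receiver"].map(type_code).to_numpy()
    lig_j = candidates["ligand"].map(gene_col).to_numpy()
    rec_j = candidates["receptor"].map(gene_col).to_numpy()

    def ratios(cvec: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        m = group_means(cvec)
        pot_case = m[send_k, 1, lig_j] * m[recv_k, 1, rec_j]
        pot_ctrl = m[send_k, 0, lig_j] * m[recv_k, 0, rec_j]
        if direction == "control-over-case":
            pot_case, pot_ctrl = pot_ctrl, pot_case
        eps = params.epsilon
        return (pot_case + eps) / (pot_ctrl + eps), pot_case, pot_ctrl

    real_ratio, pot_case, pot_ctrl = ratios(cond)

    rng = np.random.default_rng(params.seed)
    blocks = _subtype_blocks(subtypes)
    fixed = [b for b in blocks if np.unique(cond[b]).size == 1]
    if fixed:
        logger.info("%d subtype(s) hold a single condition; their labels stay fixed", len(fixed))
    rand = np.empty((params.n_permutations, len(candidates)))
    for rep in range(params.n_permutations):
        cperm = cond.copy()
        for b in blocks:
            cperm[b] = rng.permutation(cond[b])
        rand[rep], _, _ = ratios(cperm)

    mu = rand.mean(axis=0)
    sd = rand.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (real_ratio - mu) / sd
    p = normal.sf(z)
    if degenerate.any():
        logger.warning("%d candidate(s) with zero-sd null; limit p applied", int(degenerate.sum()))
        diff = real_ratio[degenerate] - mu[degenerate]
        p_deg = np.where(diff > 0, 0.0, np.where(diff < 0, 1.0, 0.5))
        p[degenerate] = p_deg
        z[degenerate] = np.where(diff > 0, np.inf, np.where(diff < 0, -np.inf, 0.0))
    q = benjamini_hochberg(p)

    out = candidates.reset_index(drop=True).copy()
    out["potential_case"] = pot_case
    out["potential_control"] = pot_ctrl
    out["ratio"] = real_ratio
    out["z"] = z
    out["p"] = p
    out["q"] = q
    out["degenerate"] = degenerate
    if return_null:
        return out, rand
    return out


def top_interactions(records: pd.DataFrame, params: LRParams | None = None) -> pd.DataFrame:
    """Per ordered type pair: q < threshold, sorted by descending ratio, top K.

    Ties in ratio break on (ligand, receptor) lexicographic order so the
    selection is deterministic.
    """
    params = params or LRParams()
    passing = records[records["q"] < params.q_threshold]
    pieces = []
    for _, grp in passing.groupby(["sender", "receiver"], sort=True):
        ordered = grp.sort_values(
            ["ratio", "ligand", "receptor"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        pieces.append(ordered.head(params.top_k))
    if not pieces:
        return records.iloc[0:0].copy()
    return pd.concat(pieces, ignore_index=True)
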