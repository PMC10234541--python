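"""Post-processing of externally produced cell-type deconvolution estimates.

The deconvolution optimizer itself is external by design; this module builds
its input (per-type mean-expression signatures), screens its output samples by
reconstruction correlation, applies the two-tier and within-group proportion
renormalizations used for display and testing, compares proportions between
conditions with grouped FDR, and implements the adjacency-difference ranking
rule for imaging-derived cell-cell interaction matrices.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .dge import EPSILON, benjamini_hochberg, rank_sum_test

__all__ = [
    "build_signature",
    "reconstruction_correlation_filter",
    "two_tier_normalize",
    "renormalize_within_group",
    "compare_proportions",
    "adjacency_difference_ranking",
]

logger = logging.getLogger(__name__)


def build_signature(
    norm: ad.AnnData,
    grouping: str = "cell_type",
    merge_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Genes x types table of per-type mean sum-normalized expression.

    ``grouping`` names the obs column holding the label level (cluster or
    subtype). ``merge_map`` pools labels before averaging (e.g. two
    disease-split inflammatory subsets grouped into one signature column).
    """
    labels = norm.obs[grouping]
    if labels.isna().any() or (labels.astype(str) == "").any():
        raise ValueError(f"unlabeled cells in obs[{grouping!r}]")
    labels = labels.astype(str)
    if merge_map:
        labels = labels.map(lambda x: merge_map.get(x, x))
    X = np.asarray(norm.X)
    cols = {}
    for t in sorted(labels.unique()):
        cols[t] = X[(labels == t).to_numpy()].mean(axis=0)
    return pd.DataFrame(cols, index=pd.Index(norm.var_names, name="gene"))


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rho with average ranks; NaN on constant input."""
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return float("nan")
    return float(stats.spearmanr(a, b).statistic)


def reconstruction_correlation_filter(
    bulk: pd.DataFrame,
    signature: pd.DataFrame,
    proportions: pd.DataFrame,
    threshold: float = 0.3,
) -> tuple[list, pd.Series]:
    """Retain bulk samples whose synthetic reconstruction correlates > threshold.

    ``bulk`` is samples x genes, ``signature`` genes x types, ``proportions``
    samples x types. The synthetic mixture of a sample is the
    proportion-weighted sum of type signatures over the gene intersection;
    samples with Spearman correlation above ``threshold`` between measured and
    synthetic profiles are retained. Undefined correlations (constant rows)
    fail the threshold with a warning. Returns (retained sample ids,
    per-sample correlation series).
    """
    shared = bulk.columns.intersection(signature.index)
    if len(shared) == 0:
        raise ValueError("bulk and signature share no genes")
    types = [t for t in proportions.columns if t in signature.columns]
    if not types:
        raise ValueError("proportions and signature share no cell types")
    sig = signature.loc[shared, types].to_numpy()
    synth = proportions[types].to_numpy() @ sig.T
    corr = {}
    for i, sample in enumerate(proportions.index):
        rho = _spearman(bulk.loc[sample, shared].to_numpy(dtype=float), synth[i])
        if np.isnan(rho):
            logger.warning("sample %s: constant profile, correlation undefined -> excluded", sample)
        corr[sample] = rho
    corr = pd.Series(corr, name="spearman")
    retained = [s for s, r in corr.items() if not np.isnan(r) and r > threshold]
    return retained, corr


def two_tier_normalize(props: pd.DataFrame, major_types: list[str]) -> pd.DataFrame:
    """Two-tier per-sample normalization of estimated proportions.

    Major types are divided by the total over all types; the remaining types
    are divided by the total after excluding the major types, so each tier is
    interpretable as a fraction of its own reference population.
    """
    missing = [t for t in major_types if t not in props.columns]
    if missing:
        raise ValueError(f"major types absent from table: {missing}")
    rest = [t for t in props.columns if t not in major_types]
    total = props.sum(axis=1)
    rest_total = props[rest].sum(axis=1)
    if (total <= 0).any() or (rest and (rest_total <= 0).any()):
        raise ValueError("a sample has zero total in a normalization tier")
    out = props.copy().astype(float)
    out[major_types] = props[major_types].div(total, axis=0)
    if rest:
        out[rest] = props[rest].div(rest_total, axis=0)
    return out


def renormalize_within_group(
    props: pd.DataFrame, group_map: dict[str, str]
) -> pd.DataFrame:
    """Divide each type's proportion by its group's per-sample sum.

    Every column must be mapped to a group. Groups with a zero sum in a sample
    yield missing values there (warned) rather than an error.
    """
    unmapped = [t for t in props.columns if t not in group_map]
    if unmapped:
        raise ValueError(f"types without a group assignment: {unmapped}")
    out = props.copy().astype(float)
    groups: dict[str, list[str]] = {}
    for t in props.columns:
        groups.setdefault(group_map[t], []).append(t)
    for g, members in groups.items():
        s = props[members].sum(axis=1)
        zero = s <= 0
        if zero.any():
            logger.warning("group %s: zero sum in samples %s", g, list(props.index[zero]))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[members] = props[members].div(s.where(~zero), axis=0)
    return out


def compare_proportions(
    props: pd.DataFrame,
    condition: pd.Series,
    family: list[str] | None = None,
    *,
    case: str = "case",
    control: str = "control",
) -> pd.DataFrame:
    """Per-type case/control comparison of sample proportions with grouped FDR.

    ``props`` is samples x types (already normalized at whatever level the
    family refers to); ``condition`` maps sample -> condition label. For each
    type in ``family`` (default: all columns) a two-sided Wilcoxon rank-sum
    test compares the per-sample values between conditions; q-values are
    Benjamini-Hochberg within the family only; fold change is the ratio of
    condition means with the module epsilon.
    """
    family = list(family) if family is not None else list(props.columns)
    missing = [t for t in family if t not in props.columns]
    if missing:
        raise ValueError(f"family members absent from table: {missing}")
    cond = condition.loc[props.index]
    case_rows = props.index[cond == case]
    ctrl_rows = props.index[cond == control]
    if len(case_rows) == 0 or len(ctrl_rows) == 0:
        raise ValueError("both conditions need at least one sample")
    rows = []
    for t in family:
        a = props.loc[case_rows, t].dropna().to_numpy(dtype=float)
        b = props.loc[ctrl_rows, t].dropna().to_numpy(dtype=float)
        fold = (a.mean() + EPSILON) / (b.mean() + EPSILON)
        rows.append((t, fold, rank_sum_test(a, b)))
    out = pd.DataFrame(rows, columns=["cell_type", "fold_change", "p"])
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def adjacency_difference_ranking(
    adj_case: pd.DataFrame,
    adj_control: pd.DataFrame,
    exclude: str = "other",
    k: int = 20,
) -> pd.DataFrame:
    """Rank imaging adjacency-interaction differences between conditions.

    Both matrices are label x label interaction-value tables with identical
    labels. Rows/columns touching the excluded label are dropped; the
    difference case - control is computed per ordered (sender, receiver)
    pair. The result stacks the top ``k`` pairs with strictly positive case
    values sorted by descending difference (direction "up") and the bottom
    ``k`` pairs with strictly negative case values sorted by ascending
    difference (direction "down").
    """
    if list(adj_case.index) != list(adj_case.columns):
        raise ValueError("adjacency matrices must be square with matching labels")
    if list(adj_case.index) != list(adj_control.index) or list(adj_case.columns) != list(
        adj_control.columns
    ):
        raise ValueError("case and control adjacency labels differ")
    keep = [l for l in adj_case.index if l != exclude]
    a = adj_case.loc[keep, keep]
    b = adj_control.loc[keep, keep]
    diff = a - b
    long = (
        diff.stack()
        .rename("difference")
        .rename_axis(["sender", "receiver"])
        .reset_index()
    )
    long["value_case"] = a.stack().to_numpy()
    long["value_control"] = b.stack().to_numpy()
    up = long[long["value_case"] > 0].sort_values(
        ["difference", "sender", "receiver"], ascending=[False, True, True], kind="mergesort"
    ).head(k)
    down = long[long["value_case"] < 0].sort_values(
        ["difference", "sender", "receiver"], ascending=[True, True, True], kind="mergesort"
    ).head(k)
    up = up.assign(direction="up")
    down = down.assign(direction="down")
    return pd.concat([up, down], ignore_index=True)
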