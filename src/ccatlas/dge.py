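"""Filtered Wilcoxon differential expression and related gene-level tests.

Within one cell type, genes are compared between case and control cells with
two-sided Wilcoxon rank-sum tests after two inclusion filters: a mean
sum-normalized expression floor (1e-4 by default, 5e-5 for sparse cell types)
computed over all cells of the type with conditions pooled, and a
subject-representation rule (expressed in at least 5 cells in each of at
least 2 subjects). Q-values are Benjamini-Hochberg within the retained gene
family of that one comparison; genes are flagged as selected when q falls
below ``q_select`` and the fold change of condition means lies above
``fc_select`` or below its reciprocal.

The module also houses one-vs-rest marker finding, marker-based annotation
transfer, a gene-set signature test, the Fisher exact proportion test, and
the GSEA-preranked ``.rnk`` export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DGEParams",
    "benjamini_hochberg",
    "rank_sum_test",
    "gene_inclusion_filter",
    "dge_wilcoxon",
    "find_markers",
    "annotate_by_reference_markers",
    "signature_test",
    "fisher_proportion_test",
    "export_rnk",
    "load_tlr4_genes",
]

logger = logging.getLogger(__name__)

#: pseudocount for fold changes on sum-normalized means, one order below the
#: smallest stated expression threshold
EPSILON = 1e-6

EXACT_MAX_N = 8


@dataclass
class DGEParams:
    min_mean_expr: float = 1e-4
    min_subjects: int = 2
    min_cells_per_subject: int = 5
    q_select: float = 0.02
    fc_select: float = 2.0

    def __post_init__(self) -> None:
        if min(self.min_mean_expr, self.q_select, self.fc_select) <= 0:
            raise ValueError("DGE thresholds must be positive")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have at most 8 observations and the
    pooled values are tie-free; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=True
        ).pvalue
    )


def _ranksum_matrix(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p-values (tie-corrected asymptotic)."""
    res = stats.mannwhitneyu(
        Xa, Xb, alternative="two-sided", method="asymptotic", use_continuity=True, axis=0
    )
    return np.asarray(res.pvalue, dtype=float)


def _type_view(norm: ad.AnnData, cell_type: str, type_key: str) -> ad.AnnData:
    if cell_type not in set(norm.obs[type_key]):
        raise ValueError(f"cell type {cell_type!r} absent from metadata")
    return norm[norm.obs[type_key] == cell_type]


def gene_inclusion_filter(
    norm: ad.AnnData,
    cell_type: str,
    params: DGEParams | None = None,
    type_key: str = "cell_type",
    subject_key: str = "patient",
) -> list[str]:
    """Genes eligible for DGE within one cell type.

    A gene is retained when its mean sum-normalized expression over all cells
    of the type (conditions pooled) exceeds ``min_mean_expr`` and it is
    expressed (>0) in at least ``min_cells_per_subject`` cells in each of at
    least ``min_subjects`` subjects.
    """
    params = params or DGEParams()
    view = _type_view(norm, cell_type, type_key)
    X = np.asarray(view.X)
    mean_ok = X.mean(axis=0) > params.min_mean_expr
    subjects = view.obs[subject_key].to_numpy()
    n_subj_ok = np.zeros(X.shape[1], dtype=int)
    for s in pd.unique(subjects):
        expressed = (X[subjects == s] > 0).sum(axis=0)
        n_subj_ok += expressed >= params.min_cells_per_subject
    keep = mean_ok & (n_subj_ok >= params.min_subjects)
    return [g for g, k in zip(view.var_names, keep) if k]


def dge_wilcoxon(
    norm: ad.AnnData,
    cell_type: str,
    params: DGEParams | None = None,
    *,
    type_key: str = "cell_type",
    subject_key: str = "patient",
    condition_key: str = "condition",
    case: str = "case",
    control: str = "control",
) -> pd.DataFrame:
    """Per-gene case/control Wilcoxon comparison within one cell type.

    Returns a DataFrame with columns gene, mean_case, mean_control,
    fold_change, log2fc, p, q, selected — one row per gene passing
    :func:`gene_inclusion_filter`, sorted by ascending p (gene name as
    tie-break). Fold change is ``(mean_case + eps) / (mean_control + eps)``
    with ``eps = 1e-6``; selection requires ``q < q_select`` and fold change
    above ``fc_select`` or below its reciprocal.
    """
    params = params or DGEParams()
    view = _type_view(norm, cell_type, type_key)
    conds = view.obs[condition_key].to_numpy()
    for label in (case, control):
        if (conds == label).sum() == 0:
            raise ValueError(
                f"condition {label!r} has no {cell_type!r} cells; comparison skipped"
            )
    genes = gene_inclusion_filter(norm, cell_type, params, type_key, subject_key)
    if not genes:
        raise ValueError(f"no genes pass the inclusion filter for {cell_type!r}")
    sub = view[:, genes]
    X = np.asarray(sub.X)
    Xa = X[conds == case]
    Xb = X[conds == control]
    if min(Xa.shape[0], Xb.shape[0]) <= EXACT_MAX_N:
        p = np.array([rank_sum_test(Xa[:, j], Xb[:, j]) for j in range(X.shape[1])])
    else:
        p = _ranksum_matrix(Xa, Xb)
    mean_case = Xa.mean(axis=0)
    mean_control = Xb.mean(axis=0)
    fc = (mean_case + EPSILON) / (mean_control + EPSILON)
    q = benjamini_hochberg(p)
    selected = (q < params.q_select) & ((fc > params.fc_select) | (fc < 1.0 / params.fc_select))
    out = pd.DataFrame(
        {
            "gene": genes,
            "mean_case": mean_case,
            "mean_control": mean_control,
            "fold_change": fc,
            "log2fc": np.log2(fc),
            "p": p,
            "q": q,
            "selected": selected,
        }
    )
    return out.sort_values(["p", "gene"], kind="mergesort", ignore_index=True)


def find_markers(
    norm: ad.AnnData,
    labels,
    logfc_min: float = 1.0,
    min_pct: float = 0.5,
) -> pd.DataFrame:
    """One-vs-rest cluster markers.

    ``labels`` is a per-cell label vector (or obs column name). A gene marks a
    cluster when the natural-log ratio of in-cluster to out-of-cluster mean
    normalized expression exceeds ``logfc_min`` (with the module epsilon) and
    the gene is expressed in at least ``min_pct`` of the cluster's cells.
    Rows are sorted per cluster by descending log fold.
    """
    if isinstance(labels, str):
        labels = norm.obs[labels]
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("marker finding needs at least 2 clusters")
    X = np.asarray(norm.X)
    rows = []
    for c in clusters:
        inside = labels == c
        mean_in = X[inside].mean(axis=0)
        mean_out = X[~inside].mean(axis=0)
        pct_in = (X[inside] > 0).mean(axis=0)
        logfc = np.log((mean_in + EPSILON) / (mean_out + EPSILON))
        keep = (logfc > logfc_min) & (pct_in >= min_pct)
        for j in np.flatnonzero(keep):
            rows.append(
                (c, norm.var_names[j], logfc[j], pct_in[j], mean_in[j], mean_out[j])
            )
    out = pd.DataFrame(
        rows, columns=["cluster", "gene", "logfc", "pct_in", "mean_in", "mean_out"]
    )
    return out.sort_values(
        ["cluster", "logfc", "gene"], ascending=[True, False, True], ignore_index=True
    )


def annotate_by_reference_markers(
    norm: ad.AnnData,
    query_labels,
    reference_markers: dict[str, list[str]],
) -> dict[str, str]:
    """Transfer reference cluster names onto query clusters by marker score.

    Each query cluster receives the reference name whose marker set has the
    highest summed mean normalized expression within that cluster. Marker
    genes missing from the gene universe are dropped with a warning; ties are
    broken lexicographically (also warned).
    """
    if not reference_markers:
        raise ValueError("reference marker map is empty")
    if isinstance(query_labels, str):
        query_labels = norm.obs[query_labels]
    query_labels = np.asarray(query_labels)
    universe = set(norm.var_names)
    present: dict[str, list[str]] = {}
    for ref, markers in reference_markers.items():
        kept = [g for g in markers if g in universe]
        missing = set(markers) - set(kept)
        if missing:
            logger.warning("reference %s: markers absent from universe: %s", ref, sorted(missing))
        present[ref] = kept
    if all(len(v) == 0 for v in present.values()):
        raise ValueError("no reference marker gene is present in the gene universe")
    X = np.asarray(norm.X)
    gene_idx = {g: i for i, g in enumerate(norm.var_names)}
    assignment: dict[str, str] = {}
    for c in sorted(pd.unique(query_labels)):
        mean_expr = X[query_labels == c].mean(axis=0)
        scores = {
            ref: float(sum(mean_expr[gene_idx[g]] for g in genes))
            for ref, genes in present.items()
        }
        best = max(scores.values())
        winners = sorted(ref for ref, s in scores.items() if s == best)
        if len(winners) > 1:
            logger.warning("cluster %s: tie between %s, keeping %s", c, winners, winners[0])
        assignment[str(c)] = winners[0]
    return assignment


def signature_test(
    norm: ad.AnnData,
    gene_set: list[str],
    *,
    condition_key: str = "condition",
    case: str = "case",
    control: str = "control",
) -> tuple[pd.Series, float]:
    """Per-cell mean expression over a gene set, compared between conditions.

    The score is the mean sum-normalized expression over the set genes present
    in the universe (absent genes are dropped with a warning); the p-value is
    a two-sided Wilcoxon rank-sum test between the case and control score
    distributions.
    """
    universe = set(norm.var_names)
    present = [g for g in gene_set if g in universe]
    missing = [g for g in gene_set if g not in universe]
    if missing:
        logger.warning("signature: %d/%d genes absent from universe", len(missing), len(gene_set))
    if not present:
        raise ValueError("gene set has empty intersection with the gene universe")
    X = np.asarray(norm[:, present].X)
    scores = pd.Series(X.mean(axis=1), index=norm.obs_names, name="signature_score")
    conds = norm.obs[condition_key].to_numpy()
    p = rank_sum_test(scores[conds == case], scores[conds == control])
    return scores, p


def fisher_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for ((k1, n1-k1), (k2, n2-k2))."""
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n):
            raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")[1])


def export_rnk(records: pd.DataFrame, path) -> None:
    """Write a GSEA-preranked two-column TSV, descending by log2 fold change.

    Ties in log2fc are broken by lexicographic gene order so the output is
    deterministic.
    """
    if records.empty:
        raise ValueError("no records to export")
    ordered = records.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
    )
    ordered[["gene", "log2fc"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6f"
    )


def load_tlr4_genes() -> list[str]:
    """The packaged REACTOME TLR4-signalling gene list (92 unique symbols)."""
    text = resources.files("ccatlas.resources").joinpath("tlr4_reactome.txt").read_text()
    seen: list[str] = []
    for line in text.splitlines():
        g = line.strip()
        if g and not g.startswith("#") and g not in seen:
            seen.append(g)
    return seen
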