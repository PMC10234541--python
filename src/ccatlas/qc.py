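"""Ambient-background subtraction, QC filter cascade, and sum-normalization.

The cascade mirrors a droplet scRNA-seq cleanup recipe:

1. per patient library, "background" droplets are those with 100-300 total
   UMIs and a raw mitochondrial fraction below 50%; the per-gene mean UMI
   count over these droplets estimates the ambient (cell-free) profile;
2. that profile is subtracted from every other droplet's counts, clipping at
   zero, and the background droplets are dropped;
3. stage 1 (per sample): cells with fewer than 200 expressed genes are
   removed, then genes expressed in fewer than 3 remaining cells;
4. stage 2 (after merging samples): cells with fewer than 1,900 UMIs, fewer
   than 1,000 expressed genes, mitochondrial fraction above 30%, or
   erythrocyte-marker fraction above 10% are removed;
5. sum-normalization divides each cell by its total, putting every downstream
   threshold on the per-cell fraction scale.

Boundary conventions: the background window is inclusive on both ends, the
"less than" / "above" filters are strict, and "expressed" means strictly
positive (post-subtraction values may be fractional).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd

from .synthetic import ERYTHROCYTE_GENES

__all__ = [
    "QCParams",
    "QCReport",
    "QCError",
    "estimate_background_profile",
    "subtract_background",
    "filter_stage1",
    "filter_stage2",
    "sum_normalize",
    "run_qc",
]

logger = logging.getLogger(__name__)


class QCError(ValueError):
    """Raised when a QC stage cannot proceed (e.g. no background cells)."""


@dataclass
class QCParams:
    bg_umi_min: int = 100
    bg_umi_max: int = 300
    bg_mito_max: float = 0.50
    min_genes_per_cell_stage1: int = 200
    min_cells_per_gene: int = 3
    min_umis: int = 1900
    min_genes_per_cell_stage2: int = 1000
    max_mito: float = 0.30
    max_erythrocyte: float = 0.10
    erythrocyte_genes: tuple[str, ...] = ERYTHROCYTE_GENES
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.bg_umi_min > self.bg_umi_max:
            raise QCError("bg_umi_min must be <= bg_umi_max")
        for name in ("bg_mito_max", "max_mito", "max_erythrocyte"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise QCError(f"{name}={v} must lie in [0, 1]")


@dataclass
class QCReport:
    """Ledger of what each stage removed; balances at every stage."""

    stages: list[dict] = field(default_factory=list)
    background: dict = field(default_factory=dict)

    def add_stage(self, name: str, *, cells_in: int, cells_removed: int,
                  genes_in: int, genes_removed: int, reasons: dict | None = None) -> None:
        self.stages.append(
            {
                "stage": name,
                "cells_in": cells_in,
                "cells_removed": cells_removed,
                "cells_out": cells_in - cells_removed,
                "genes_in": genes_in,
                "genes_removed": genes_removed,
                "genes_out": genes_in - genes_removed,
                "reasons": reasons or {},
            }
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _dense(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if not isinstance(X, np.ndarray):
        X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    return X


def mito_mask(var_names, prefix: str = "MT-") -> np.ndarray:
    return np.asarray([g.startswith(prefix) for g in var_names], dtype=bool)


def erythrocyte_mask(var_names, genes=ERYTHROCYTE_GENES) -> np.ndarray:
    gene_set = set(genes)
    return np.asarray([g in gene_set for g in var_names], dtype=bool)


def estimate_background_profile(
    adata: ad.AnnData, params: QCParams | None = None
) -> tuple[pd.Series, pd.Index]:
    """Per-gene mean UMI count over background droplets, plus their ids.

    Background droplets are those with total counts in the inclusive window
    ``[bg_umi_min, bg_umi_max]`` and raw mitochondrial fraction strictly below
    ``bg_mito_max``. Raises :class:`QCError` when no droplet qualifies, in
    which case the caller should skip subtraction and flag it in the report.
    """
    params = params or QCParams()
    X = _dense(adata)
    totals = X.sum(axis=1)
    mito = mito_mask(adata.var_names, params.mito_prefix)
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(totals > 0, X[:, mito].sum(axis=1) / np.maximum(totals, 1e-300), 0.0)
    in_window = (totals >= params.bg_umi_min) & (totals <= params.bg_umi_max)
    bg = in_window & (mito_frac < params.bg_mito_max)
    if not bg.any():
        raise QCError("no background cells in the 100-300 UMI window; skip subtraction")
    profile = pd.Series(X[bg].mean(axis=0), index=adata.var_names, name="background_mean")
    return profile, adata.obs_names[bg]


def subtract_background(
    adata: ad.AnnData, profile: pd.Series, background_ids: pd.Index | None = None
) -> ad.AnnData:
    """Subtract the per-gene background mean from every non-background cell.

    Values clip at zero (negative expression is meaningless and clipping
    preserves downstream rank tests); output values may be fractional.
    Background cells are dropped from the output.
    """
    if not profile.index.equals(pd.Index(adata.var_names)):
        raise QCError("background profile index does not match the gene index")
    keep = (
        ~adata.obs_names.isin(background_ids)
        if background_ids is not None
        else np.ones(adata.n_obs, dtype=bool)
    )
    out = adata[keep].copy()
    out.X = np.maximum(_dense(out) - profile.to_numpy()[None, :], 0.0)
    return out


def filter_stage1(
    adata: ad.AnnData, params: QCParams | None = None
) -> tuple[ad.AnnData, dict]:
    """Per-sample filter: cells with <200 expressed genes, then genes in <3 cells."""
    params = params or QCParams()
    X = _dense(adata)
    genes_per_cell = (X > 0).sum(axis=1)
    keep_cells = genes_per_cell >= params.min_genes_per_cell_stage1
    X2 = X[keep_cells]
    cells_per_gene = (X2 > 0).sum(axis=0)
    keep_genes = cells_per_gene >= params.min_cells_per_gene
    out = adata[keep_cells, keep_genes].copy()
    stage = {
        "stage": "stage1",
        "cells_in": adata.n_obs,
        "cells_removed": int((~keep_cells).sum()),
        "cells_out": out.n_obs,
        "genes_in": adata.n_vars,
        "genes_removed": int((~keep_genes).sum()),
        "genes_out": out.n_vars,
        "reasons": {
            "low_gene_cells": int((~keep_cells).sum()),
            "low_cell_genes": int((~keep_genes).sum()),
        },
    }
    if out.n_obs == 0 or out.n_vars == 0:
        raise QCError(f"stage1 removed everything: {stage}")
    return out, stage


def filter_stage2(
    adata: ad.AnnData, params: QCParams | None = None
) -> tuple[ad.AnnData, dict]:
    """Merged-matrix filter: depth, gene count, mito and erythrocyte fractions.

    Keeps cells with total >= ``min_umis``, expressed genes >=
    ``min_genes_per_cell_stage2``, mitochondrial fraction <= ``max_mito`` and
    erythrocyte fraction <= ``max_erythrocyte``, all on current (possibly
    post-subtraction) values. The reasons ledger counts a cell once per
    violated criterion; the cell is removed once.
    """
    params = params or QCParams()
    X = _dense(adata)
    totals = X.sum(axis=1)
    genes_per_cell = (X > 0).sum(axis=1)
    mito = mito_mask(adata.var_names, params.mito_prefix)
    ery = erythrocyte_mask(adata.var_names, params.erythrocyte_genes)
    safe = np.maximum(totals, 1e-300)
    mito_frac = X[:, mito].sum(axis=1) / safe
    ery_frac = X[:, ery].sum(axis=1) / safe
    fail_umis = totals < params.min_umis
    fail_genes = genes_per_cell < params.min_genes_per_cell_stage2
    fail_mito = mito_frac > params.max_mito
    fail_ery = ery_frac > params.max_erythrocyte
    keep = ~(fail_umis | fail_genes | fail_mito | fail_ery)
    out = adata[keep].copy()
    stage = {
        "stage": "stage2",
        "cells_in": adata.n_obs,
        "cells_removed": int((~keep).sum()),
        "cells_out": out.n_obs,
        "genes_in": adata.n_vars,
        "genes_removed": 0,
        "genes_out": adata.n_vars,
        "reasons": {
            "low_umis": int(fail_umis.sum()),
            "low_genes": int(fail_genes.sum()),
            "high_mito": int(fail_mito.sum()),
            "high_erythrocyte": int(fail_ery.sum()),
        },
    }
    if out.n_obs == 0:
        raise QCError(f"stage2 removed every cell: {stage}")
    return out, stage


def sum_normalize(adata: ad.AnnData) -> ad.AnnData:
    """Divide each cell by its total so every row sums to 1 (idempotent)."""
    X = _dense(adata)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        offenders = list(adata.obs_names[totals <= 0][:5])
        raise QCError(f"cannot sum-normalize all-zero cells, e.g. {offenders}")
    out = adata.copy()
    out.X = X / totals[:, None]
    return out


def run_qc(
    adata: ad.AnnData,
    params: QCParams | None = None,
    sample_key: str = "patient",
) -> tuple[ad.AnnData, QCReport]:
    """Full cascade: per-sample background subtraction + stage 1, merge, stage 2.

    Background estimation and the stage-1 filters run independently within
    each sample (patient library); samples are then merged on the union of
    surviving genes (absent genes fill with zero) and the stage-2 filters run
    on the merged matrix.
    """
    params = params or QCParams()
    report = QCReport()
    pieces = []
    n_background = 0
    for sample in pd.unique(adata.obs[sample_key]):
        sub = adata[adata.obs[sample_key] == sample].copy()
        try:
            profile, bg_ids = estimate_background_profile(sub, params)
        except QCError:
            logger.warning("sample %s: no background cells, skipping subtraction", sample)
            report.background[str(sample)] = {"n_background_cells": 0, "subtracted": False}
            cleaned = sub
        else:
            cleaned = subtract_background(sub, profile, bg_ids)
            report.background[str(sample)] = {
                "n_background_cells": int(len(bg_ids)),
                "subtracted": True,
                "profile_checksum": hashlib.sha256(
                    np.ascontiguousarray(profile.to_numpy()).tobytes()
                ).hexdigest()[:16],
            }
            n_background += len(bg_ids)
        filtered, stage = filter_stage1(cleaned, params)
        stage["stage"] = f"stage1[{sample}]"
        report.stages.append(stage)
        pieces.append(filtered)
    merged = ad.concat(pieces, join="outer", fill_value=0.0, merge="same")
    merged.obs = adata.obs.loc[merged.obs_names].copy()
    report.background["total_background_cells"] = int(n_background)
    final, stage2 = filter_stage2(merged, params)
    report.stages.append(stage2)
    return final, report
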