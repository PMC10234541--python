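"""Signature stability under patient subsampling and cell subsampling.

A cell type's expression signature is its per-type mean sum-normalized
profile. The reference signature is computed once on the full data for one
condition, together with a per-type gene mask keeping genes whose reference
mean exceeds an expression floor (5e-6 by default); the same mask is reused
for every subsample so curves stay comparable.

Two resampling designs probe robustness:

* **patient subsampling** — for every combination of n patients (n below the
  full count), cells of the selected patients are bootstrap-resampled (with
  replacement) a fixed number of times, signatures recomputed, and the
  Spearman correlation with the reference recorded per cell type; the
  full-patient point bootstraps all cells. Cell types not represented by at
  least ``min_cells`` cells in at least ``min_patients_represented`` patients
  are excluded.
* **cell subsampling control** — equally sized cell subsets drawn uniformly
  while ignoring patient identity; the per-size summary is the median over
  bootstrap draws. Matching these sizes to the mean depth of each
  patient-combination stratum separates the effect of patient count from the
  effect of cell count.
"""

from __future__ import annotations

import logging
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "reference_signature",
    "patient_subsample_stability",
    "cell_subsample_control",
    "matched_cell_sizes",
]

logger = logging.getLogger(__name__)


def _signature_matrix(X: np.ndarray, types_vec: np.ndarray, types: list[str]) -> dict[str, np.ndarray]:
    out = {}
    for t in types:
        rows = types_vec == t
        if rows.any():
            out[t] = X[rows].mean(axis=0)
    return out


def reference_signature(
    norm: ad.AnnData,
    condition_subset: str,
    expr_floor: float = 5e-6,
    *,
    type_key: str = "cell_type",
    condition_key: str = "condition",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference per-type signature on one condition, plus the gene mask.

    Returns ``(signature, mask)``: genes x types mean normalized expression
    over the condition's cells, and a boolean genes x types frame marking the
    genes whose reference mean exceeds ``expr_floor`` for that type. The mask
    is fixed by the reference and reused for all subsamples.
    """
    sel = norm.obs[condition_key] == condition_subset
    if not sel.any():
        raise ValueError(f"no cells in condition {condition_subset!r}")
    view = norm[sel]
    X = np.asarray(view.X)
    tvec = view.obs[type_key].to_numpy()
    types = sorted(pd.unique(tvec))
    sig = _signature_matrix(X, tvec, types)
    signature = pd.DataFrame(sig, index=pd.Index(norm.var_names, name="gene"))
    mask = signature > expr_floor
    empty = [t for t in signature.columns if not mask[t].any()]
    if empty:
        raise ValueError(f"empty gene mask for cell type(s) {empty}; lower expr_floor")
    return signature, mask


def _masked_spearman(ref: np.ndarray, sub: np.ndarray, mask: np.ndarray) -> float:
    a, b = ref[mask], sub[mask]
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return float("nan")
    return float(stats.spearmanr(a, b).statistic)


def _eligible_types(
    tvec: np.ndarray, pvec: np.ndarray, min_cells: int, min_patients: int
) -> list[str]:
    counts = pd.crosstab(pd.Series(tvec), pd.Series(pvec))
    return sorted(t for t in counts.index if int((counts.loc[t] >= min_cells).sum()) >= min_patients)


def patient_subsample_stability(
    norm: ad.AnnData,
    reference: pd.DataFrame,
    mask: pd.DataFrame,
    *,
    condition_subset: str | None = None,
    n_range: list[int] | None = None,
    bootstraps_per_combo: int = 3,
    min_cells: int = 10,
    min_patients_represented: int = 4,
    seed: int = 0,
    type_key: str = "cell_type",
    patient_key: str = "patient",
    condition_key: str = "condition",
) -> pd.DataFrame:
    """Stability curve over the number of patients sampled.

    Returns a tidy frame (mode, n_patients, combo, replicate, cell_type,
    spearman, n_cells). Deterministic given ``seed``. ``n_range`` defaults to
    1..P-1 where P is the number of patients in the analyzed condition; the
    full-patient point (n = P) is always added by bootstrapping all cells.
    """
    view = norm
    if condition_subset is not None:
        view = norm[norm.obs[condition_key] == condition_subset]
    X = np.asarray(view.X)
    tvec = view.obs[type_key].to_numpy()
    pvec = view.obs[patient_key].to_numpy()
    patients = sorted(pd.unique(pvec))
    P = len(patients)
    if P < 2:
        raise ValueError("patient subsampling needs at least 2 patients")
    n_range = list(n_range) if n_range is not None else list(range(1, P))
    if any(n < 1 or n > P for n in n_range):
        raise ValueError(f"n_range values must lie in [1, {P}]")
    eligible = _eligible_types(tvec, pvec, min_cells, min_patients_represented)
    if not eligible:
        raise ValueError("no cell type passes the representation rule")

    rng = np.random.default_rng(seed)
    ref = {t: reference[t].to_numpy() for t in eligible}
    msk = {t: mask[t].to_numpy() for t in eligible}
    rows = []

    def record(cells: np.ndarray, n: int, combo: str, rep: int) -> None:
        resampled = rng.choice(cells, size=cells.size, replace=True)
        sig = _signature_matrix(X[resampled], tvec[resampled], eligible)
        for t in eligible:
            if t not in sig:
                logger.info("combo %s rep %d: cell type %s absent", combo, rep, t)
                continue
            rows.append(
                (
                    "patient_subsample",
                    n,
                    combo,
                    rep,
                    t,
                    _masked_spearman(ref[t], sig[t], msk[t]),
                    cells.size,
                )
            )

    for n in sorted(set(n_range)):
        for combo in combinations(patients, n):
            cells = np.flatnonzero(np.isin(pvec, combo))
            if cells.size == 0:
                continue
            for rep in range(bootstraps_per_combo):
                record(cells, n, "+".join(combo), rep)
    all_cells = np.arange(X.shape[0])
    for rep in range(bootstraps_per_combo):
        record(all_cells, P, "+".join(patients), rep)
    return pd.DataFrame(
        rows,
        columns=["mode", "n_patients", "combo", "replicate", "cell_type", "spearman", "n_cells"],
    )


def cell_subsample_control(
    norm: ad.AnnData,
    reference: pd.DataFrame,
    mask: pd.DataFrame,
    sizes: list[int],
    *,
    condition_subset: str | None = None,
    bootstraps: int = 20,
    seed: int = 0,
    type_key: str = "cell_type",
    condition_key: str = "condition",
) -> pd.DataFrame:
    """Stability control at fixed cell counts, ignoring patient identity.

    For each size, draws ``bootstraps`` uniform cell subsets (without
    replacement), recomputes per-type signatures and the masked Spearman
    correlation with the reference. Returns the same tidy layout as
    :func:`patient_subsample_stability` with mode ``cell_subsample_control``
    and the subset size on the ``n_cells`` axis.
    """
    view = norm
    if condition_subset is not None:
        view = norm[norm.obs[condition_key] == condition_subset]
    X = np.asarray(view.X)
    tvec = view.obs[type_key].to_numpy()
    total = X.shape[0]
    types = [t for t in reference.columns]
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size <= 0:
            raise ValueError("subset size must be positive")
        if size > total:
            raise ValueError(f"subset size {size} exceeds {total} cells")
        for rep in range(bootstraps):
            chosen = rng.choice(total, size=size, replace=False)
            sig = _signature_matrix(X[chosen], tvec[chosen], types)
            for t in types:
                if t not in sig:
                    continue
                rows.append(
                    (
                        "cell_subsample_control",
                        np.nan,
                        str(size),
                        rep,
                        t,
                        _masked_spearman(
                            reference[t].to_numpy(), sig[t], mask[t].to_numpy()
                        ),
                        size,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["mode", "n_patients", "combo", "replicate", "cell_type", "spearman", "n_cells"],
    )


def matched_cell_sizes(curve: pd.DataFrame) -> dict[int, int]:
    """Mean cell count per patient-count stratum of a patient-subsample curve.

    Used to hand the cell-subsample control sizes comparable to each patient
    stratum's depth.
    """
    strata = curve.drop_duplicates(["n_patients", "combo"])
    return {
        int(n): int(round(grp["n_cells"].mean()))
        for n, grp in strata.groupby("n_patients")
    }
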