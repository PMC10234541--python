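"""End-to-end pipeline driver: QC -> normalize -> DGE -> LR -> stability (-> composition).

The pipeline is a pure function of (inputs, config, seed): rerunning with the
same configuration produces byte-identical result files. A machine-readable
manifest records every parameter, seed and stage ledger so any stage can be
reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import composition as comp
from . import dge as dge_mod
from . import io as io_mod
from . import lr as lr_mod
from . import stability as stab_mod
from .qc import QCParams, run_qc, sum_normalize
from .dge import DGEParams
from .lr import LRParams

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    counts_path: str
    metadata_path: str
    lr_table_path: str | None = None
    bulk_path: str | None = None
    proportions_path: str | None = None
    out_dir: str = "results"
    seed: int = 0
    case: str = "case"
    control: str = "control"
    dge_cell_types: list[str] | None = None
    stability_condition: str = "case"
    stability_bootstraps: int = 3
    stability_min_cells: int = 10
    stability_min_patients: int = 4
    qc: QCParams = field(default_factory=QCParams)
    dge: DGEParams = field(default_factory=DGEParams)
    lr: LRParams = field(default_factory=LRParams)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, klass in (("qc", QCParams), ("dge", DGEParams), ("lr", LRParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for label, p in (("counts", self.counts_path), ("metadata", self.metadata_path),
                         ("lr table", self.lr_table_path), ("bulk", self.bulk_path),
                         ("proportions", self.proportions_path)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the result bundle (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_manifest(), "stages": {}}
    bundle: dict = {}

    def fail(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- load + QC -------------------------------------------------------
    try:
        adata = io_mod.load_dataset(config.counts_path, config.metadata_path)
        clean, report = run_qc(adata, config.qc)
        report.to_json(out / "qc_report.json")
        norm = sum_normalize(clean)
        manifest["stages"]["qc"] = {
            "status": "ok",
            "cells_in": int(adata.n_obs),
            "cells_out": int(clean.n_obs),
            "genes_out": int(clean.n_vars),
        }
        bundle["qc_report"] = report
        bundle["normalized"] = norm
    except Exception as exc:  # noqa: BLE001 - stage name must propagate
        fail("qc", exc)

    cond = norm.obs["condition"]
    kw = dict(case=config.case, control=config.control)

    # ---- DGE -------------------------------------------------------------
    try:
        types = config.dge_cell_types or sorted(norm.obs["cell_type"].unique())
        dge_tables = {}
        for t in types:
            n_case = int(((norm.obs["cell_type"] == t) & (cond == config.case)).sum())
            n_ctrl = int(((norm.obs["cell_type"] == t) & (cond == config.control)).sum())
            if min(n_case, n_ctrl) == 0:
                logger.warning("cell type %s underrepresented in one condition; skipped", t)
                continue
            table = dge_mod.dge_wilcoxon(norm, t, config.dge, **kw)
            dge_tables[t] = table
            safe = t.replace("/", "_")
            _write_csv(table, out / f"dge_{safe}.csv")
            dge_mod.export_rnk(table, out / f"dge_{safe}.rnk")
        manifest["stages"]["dge"] = {"status": "ok", "cell_types": sorted(dge_tables)}
        bundle["dge"] = dge_tables
    except Exception as exc:
        fail("dge", exc)

    # ---- ligand-receptor ---------------------------------------------------
    if config.lr_table_path:
        try:
            pairs = io_mod.load_lr_table(config.lr_table_path)
            lr_params = dataclasses.replace(config.lr, seed=config.seed)
            cands = lr_mod.candidate_interactions(norm, pairs, lr_params, **kw)
            records = lr_mod.permutation_test(norm, cands, lr_params, **kw)
            top = lr_mod.top_interactions(records, lr_params)
            _write_csv(records, out / "lr_records.csv")
            _write_csv(top, out / "lr_top.csv")
            manifest["stages"]["lr"] = {
                "status": "ok",
                "n_candidates": int(len(cands)),
                "n_selected": int(len(top)),
                "seed": lr_params.seed,
            }
            bundle["lr_records"] = records
            bundle["lr_top"] = top
        except Exception as exc:
            fail("lr", exc)
    else:
        manifest["stages"]["lr"] = {"status": "skipped", "reason": "no pair table given"}

    # ---- stability ---------------------------------------------------------
    try:
        reference, mask = stab_mod.reference_signature(norm, config.stability_condition)
        n_patients = norm.obs.loc[
            (cond == config.stability_condition).to_numpy(), "patient"
        ].nunique()
        curve = stab_mod.patient_subsample_stability(
            norm,
            reference,
            mask,
            condition_subset=config.stability_condition,
            bootstraps_per_combo=config.stability_bootstraps,
            min_cells=config.stability_min_cells,
            # the representation rule cannot demand more patients than exist
            min_patients_represented=min(config.stability_min_patients, n_patients),
            seed=config.seed,
        )
        sizes = sorted(set(stab_mod.matched_cell_sizes(curve).values()))
        control_curve = stab_mod.cell_subsample_control(
            norm,
            reference,
            mask,
            sizes,
            condition_subset=config.stability_condition,
            seed=config.seed + 1,
        )
        all_curves = pd.concat([curve, control_curve], ignore_index=True)
        _write_csv(all_curves, out / "stability.csv")
        manifest["stages"]["stability"] = {"status": "ok", "n_rows": int(len(all_curves))}
        bundle["stability"] = all_curves
    except Exception as exc:
        fail("stability", exc)

    # ---- composition ---------------------------------------------------------
    if config.bulk_path and config.proportions_path:
        try:
            bulk = pd.read_csv(config.bulk_path, index_col=0)
            props = pd.read_csv(config.proportions_path, index_col=0)
            signature = comp.build_signature(norm, "cell_type")
            retained, corr = comp.reconstruction_correlation_filter(bulk, signature, props)
            sample_cond = (
                norm.obs.groupby("patient", observed=True)["condition"].first()
                if set(props.index) <= set(norm.obs["patient"])
                else None
            )
            comp_out = {"retained_samples": retained, "correlations": corr}
            corr.rename_axis("sample").reset_index().to_csv(
                out / "composition_correlations.csv", index=False, float_format=FLOAT_FORMAT
            )
            if sample_cond is not None and retained:
                kept = props.loc[retained]
                stats_table = comp.compare_proportions(
                    kept, sample_cond, case=config.case, control=config.control
                )
                _write_csv(stats_table, out / "composition_comparison.csv")
                comp_out["comparison"] = stats_table
            manifest["stages"]["composition"] = {
                "status": "ok",
                "n_retained": len(retained),
            }
            bundle["composition"] = comp_out
        except Exception as exc:
            fail("composition", exc)
    else:
        manifest["stages"]["composition"] = {
            "status": "skipped",
            "reason": "bulk/proportions inputs not given",
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["manifest"] = manifest
    return bundle
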