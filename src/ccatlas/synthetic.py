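"""Synthetic multi-patient case/control droplet atlas with planted ground truth.

The generator emulates the data regime of a two-condition droplet scRNA-seq
study: negative-binomial counts with cell-type marker structure, ambient
(cell-free) contamination mixed into every real cell, empty droplets carrying
100-300 UMIs of pure ambient material, mitochondrial and erythrocyte gene
content, patient-level mean jitter, and optional planted differential
expression and planted ligand-receptor up-regulation. Every emitted droplet
carries an exact truth label, so the QC cascade, the Wilcoxon differential
expression, the ligand-receptor permutation statistic, and the stability
curves can all be scored against known answers without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "ERYTHROCYTE_GENES",
    "PlantedDE",
    "PlantedLR",
    "SyntheticSpec",
    "GroundTruth",
    "generate_atlas",
    "generate_lr_table",
    "generate_bulk_mixtures",
]

#: Erythrocyte marker symbols screened by the QC cascade (haemoglobin chains
#: plus AHSP); kept verbatim so downstream list filters apply unchanged.
ERYTHROCYTE_GENES = ("HBG2", "HBA2", "HBA1", "HBB", "HBG1", "HBM", "AHSP", "HBZ")

CONDITION_CASE = "case"
CONDITION_CONTROL = "control"
EMPTY_LABEL = "empty"


class ConfigurationError(ValueError):
    """Raised when a synthetic specification is internally inconsistent."""


@dataclass(frozen=True)
class PlantedDE:
    """A gene whose mean expression is multiplied by ``fold`` in case cells of one type."""

    gene: str
    cell_type: str
    fold: float


@dataclass(frozen=True)
class PlantedLR:
    """A ligand-receptor pair up-regulated in case cells.

    ``ligand_fold`` multiplies the ligand mean in case cells of the sender
    type; ``receptor_fold`` does the same for the receptor in the receiver
    type. A fold of 1.0 leaves that side untouched.
    """

    ligand: str
    receptor: str
    sender: str
    receiver: str
    ligand_fold: float = 1.0
    receptor_fold: float = 1.0


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic atlas.

    Defaults describe a 4-type, 5+5-patient atlas with ~4,000 UMIs per real
    cell, 10% ambient contamination and 40 empty droplets per patient. Gene
    baseline means are lognormal around ``baseline_mean`` (genes span orders
    of magnitude in real data); genes participating in planted effects are
    pinned to ``baseline_mean`` exactly so planted folds are not confounded
    with the random mean draw.
    """

    n_genes: int = 2000
    n_cell_types: int = 4
    cells_per_type_per_patient: int = 100
    n_patients_case: int = 5
    n_patients_control: int = 5
    marker_genes_per_type: int = 20
    marker_fold: float = 8.0
    baseline_mean: float = 2.0
    gene_mean_lognormal_sigma: float = 1.0
    nb_dispersion: float = 10.0
    library_size_lognormal_sigma: float = 0.25
    ambient_fraction: float = 0.10
    n_empty_droplets_per_patient: int = 40
    empty_droplet_umi_range: tuple[int, int] = (100, 300)
    mito_gene_count: int = 10
    mito_mean_factor: float = 8.0
    erythrocyte_genes: tuple[str, ...] = ERYTHROCYTE_GENES
    subtypes_per_type: int = 1
    patient_jitter_sigma: float = 0.05
    n_high_mito_per_patient: int = 3
    n_high_ery_per_patient: int = 3
    high_mito_fraction: float = 0.50
    high_ery_fraction: float = 0.25
    planted_de: list[PlantedDE] = field(default_factory=list)
    planted_lr: list[PlantedLR] = field(default_factory=list)
    seed: int = 0

    # ---- derived naming -------------------------------------------------
    def gene_names(self) -> list[str]:
        n_special = len(self.erythrocyte_genes) + self.mito_gene_count
        if self.n_genes <= n_special:
            raise ConfigurationError(
                f"n_genes={self.n_genes} must exceed the "
                f"{n_special} mitochondrial/erythrocyte genes"
            )
        mito = [f"MT-G{i + 1}" for i in range(self.mito_gene_count)]
        n_generic = self.n_genes - n_special
        width = max(4, len(str(n_generic)))
        generic = [f"G{i + 1:0{width}d}" for i in range(n_generic)]
        return list(self.erythrocyte_genes) + mito + generic

    def cell_type_names(self) -> list[str]:
        return [f"type{i + 1}" for i in range(self.n_cell_types)]

    def patient_names(self) -> list[tuple[str, str]]:
        """(patient id, condition) in a fixed order: cases first."""
        pts = [(f"case_p{i + 1}", CONDITION_CASE) for i in range(self.n_patients_case)]
        pts += [
            (f"ctrl_p{i + 1}", CONDITION_CONTROL)
            for i in range(self.n_patients_control)
        ]
        return pts

    def validate(self) -> None:
        if min(self.n_genes, self.n_cell_types, self.cells_per_type_per_patient) <= 0:
            raise ConfigurationError("gene/type/cell counts must be positive")
        if self.n_patients_case <= 0 or self.n_patients_control <= 0:
            raise ConfigurationError("both conditions need at least one patient")
        if not (0.0 <= self.ambient_fraction <= 1.0):
            raise ConfigurationError("ambient_fraction must lie in [0, 1]")
        lo, hi = self.empty_droplet_umi_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"empty_droplet_umi_range {self.empty_droplet_umi_range} must satisfy 1 <= lo <= hi"
            )
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise ConfigurationError("baseline_mean and nb_dispersion must be positive")
        if self.library_size_lognormal_sigma < 0 or self.patient_jitter_sigma < 0:
            raise ConfigurationError("lognormal sigmas must be non-negative")
        genes = set(self.gene_names())
        types = set(self.cell_type_names())
        n_markers = self.n_cell_types * self.marker_genes_per_type
        n_generic = self.n_genes - len(self.erythrocyte_genes) - self.mito_gene_count
        if n_markers > n_generic:
            raise ConfigurationError("not enough generic genes for the requested markers")
        for p in self.planted_de:
            if p.fold <= 0:
                raise ConfigurationError(f"planted DE fold must be positive: {p}")
            if p.gene not in genes:
                raise ConfigurationError(f"planted DE gene {p.gene!r} not in gene universe")
            if p.cell_type not in types:
                raise ConfigurationError(f"planted DE type {p.cell_type!r} not in type universe")
        for p in self.planted_lr:
            if p.ligand_fold <= 0 or p.receptor_fold <= 0:
                raise ConfigurationError(f"planted LR folds must be positive: {p}")
            for g in (p.ligand, p.receptor):
                if g not in genes:
                    raise ConfigurationError(f"planted LR gene {g!r} not in gene universe")
            for t in (p.sender, p.receiver):
                if t not in types:
                    raise ConfigurationError(f"planted LR type {t!r} not in type universe")


@dataclass
class GroundTruth:
    """Bookkeeping truth for one generated atlas (exact, not estimated)."""

    genes: list[str]
    cell_types: list[str]
    #: per-gene ambient probability vector, sums to 1
    ambient_profile: pd.Series
    #: per-droplet truth label: "real" or "empty"
    droplet_label: pd.Series
    #: per-droplet planted QC failure mode: "", "high_mito" or "high_erythrocyte"
    qc_fail: pd.Series
    #: expected own-material counts per gene, keyed (cell_type, condition)
    expected_expression: dict[tuple[str, str], np.ndarray]
    planted_de: list[PlantedDE]
    planted_lr: list[PlantedLR]

    def expected_mean_frame(self, condition: str) -> pd.DataFrame:
        """Genes x types table of expected own-profile mean counts."""
        cols = {
            t: self.expected_expression[(t, condition)] for t in self.cell_types
        }
        return pd.DataFrame(cols, index=self.genes)

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "cell_types": self.cell_types,
            "ambient_profile": self.ambient_profile.to_dict(),
            "droplet_label": self.droplet_label.to_dict(),
            "qc_fail": self.qc_fail.to_dict(),
            "expected_expression": {
                f"{t}|{c}": v.tolist() for (t, c), v in self.expected_expression.items()
            },
            "planted_de": [asdict(p) for p in self.planted_de],
            "planted_lr": [asdict(p) for p in self.planted_lr],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _base_gene_means(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Baseline expected counts per gene, shared across cell types.

    Generic genes draw a mean-one lognormal factor; mitochondrial genes sit at
    ``mito_mean_factor`` times baseline; erythrocyte genes, marker genes and
    planted genes are pinned to the plain baseline.
    """
    genes = spec.gene_names()
    sig = spec.gene_mean_lognormal_sigma
    factors = np.exp(rng.normal(0.0, sig, size=len(genes)) - 0.5 * sig**2)
    base = spec.baseline_mean * factors
    n_ery = len(spec.erythrocyte_genes)
    base[:n_ery] = spec.baseline_mean
    base[n_ery : n_ery + spec.mito_gene_count] = (
        spec.baseline_mean * spec.mito_mean_factor
    )
    name_to_idx = {g: i for i, g in enumerate(genes)}
    pinned = {p.gene for p in spec.planted_de}
    for p in spec.planted_lr:
        pinned.update((p.ligand, p.receptor))
    for g in pinned:
        base[name_to_idx[g]] = spec.baseline_mean
    return base


def _marker_assignment(spec: SyntheticSpec) -> dict[str, list[int]]:
    """Deterministic marker gene indices per cell type (disjoint blocks).

    Markers are taken from the tail of the generic-gene block so they never
    collide with planted genes supplied by the caller (callers conventionally
    plant on early generic genes; collisions are legal, just overlapping).
    """
    genes = spec.gene_names()
    n = len(genes)
    per = spec.marker_genes_per_type
    out: dict[str, list[int]] = {}
    start = n - spec.n_cell_types * per
    for k, t in enumerate(spec.cell_type_names()):
        out[t] = list(range(start + k * per, start + (k + 1) * per))
    return out


def _expected_profiles(
    spec: SyntheticSpec, base: np.ndarray
) -> dict[tuple[str, str], np.ndarray]:
    """Expected own-material mean counts per (cell type, condition)."""
    markers = _marker_assignment(spec)
    name_to_idx = {g: i for i, g in enumerate(spec.gene_names())}
    profiles: dict[tuple[str, str], np.ndarray] = {}
    for t in spec.cell_type_names():
        prof = base.copy()
        prof[markers[t]] *= spec.marker_fold
        profiles[(t, CONDITION_CONTROL)] = prof
        case = prof.copy()
        for p in spec.planted_de:
            if p.cell_type == t:
                case[name_to_idx[p.gene]] *= p.fold
        for p in spec.planted_lr:
            if p.sender == t:
                case[name_to_idx[p.ligand]] *= p.ligand_fold
            if p.receiver == t:
                case[name_to_idx[p.receptor]] *= p.receptor_fold
        profiles[(t, CONDITION_CASE)] = case
    return profiles


def _boost_fraction(mu: np.ndarray, idx: np.ndarray, target: float) -> np.ndarray:
    """Rescale ``mu[idx]`` so that group's share of the total equals ``target``."""
    out = mu.copy()
    inside = out[idx].sum()
    outside = out.sum() - inside
    if inside <= 0:
        raise ConfigurationError("cannot boost a zero-mean gene group")
    out[idx] *= target * outside / ((1.0 - target) * inside)
    return out


def generate_atlas(spec: SyntheticSpec) -> tuple[ad.AnnData, GroundTruth]:
    """Generate one atlas: counts + per-cell metadata + exact ground truth.

    Returns an :class:`anndata.AnnData` with raw integer counts (cells x
    genes; ``obs`` columns ``patient``, ``condition``, ``cell_type``,
    ``cell_subtype``) and the matching :class:`GroundTruth`. Deterministic
    given ``spec.seed``: the same spec yields bit-identical matrices.

    Real cells draw a mean-one lognormal library factor; their per-gene means
    mix own material with the ambient profile at ``ambient_fraction``, so the
    expected total stays equal to the drawn library size. Counts are
    gamma-Poisson (negative binomial with shared dispersion). Empty droplets
    draw a uniform total in ``empty_droplet_umi_range`` and a multinomial
    composition from the ambient profile.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names()
    types = spec.cell_type_names()
    patients = spec.patient_names()
    n_genes = len(genes)

    base = _base_gene_means(spec, rng)
    profiles = _expected_profiles(spec, base)

    sig_p = spec.patient_jitter_sigma
    jitter = {
        pid: np.exp(rng.normal(0.0, sig_p, size=n_genes) - 0.5 * sig_p**2)
        if sig_p > 0
        else np.ones(n_genes)
        for pid, _ in patients
    }

    n_ery = len(spec.erythrocyte_genes)
    ery_idx = np.arange(n_ery)
    mito_idx = np.arange(n_ery, n_ery + spec.mito_gene_count)

    # ambient truth: expression-weighted mean of every real cell's expected
    # own profile (jitter is mean-one, so patient factors are left out)
    ambient_raw = np.zeros(n_genes)
    n_per = spec.cells_per_type_per_patient
    for pid, cond in patients:
        for t in types:
            ambient_raw += n_per * profiles[(t, cond)]
    for pid, cond in patients:
        for kind, n_fail, frac, idx in (
            ("high_mito", spec.n_high_mito_per_patient, spec.high_mito_fraction, mito_idx),
            ("high_erythrocyte", spec.n_high_ery_per_patient, spec.high_ery_fraction, ery_idx),
        ):
            for j in range(n_fail):
                t = types[j % len(types)]
                ambient_raw += _boost_fraction(profiles[(t, cond)], idx, frac)
    ambient_profile = ambient_raw / ambient_raw.sum()

    # ---- assemble droplets ---------------------------------------------
    mu_rows: list[np.ndarray] = []
    obs_rows: list[tuple[str, str, str, str, str]] = []  # id, patient, cond, type, subtype
    truth_label: list[str] = []
    qc_fail: list[str] = []

    def subtype_of(t: str, i: int) -> str:
        if spec.subtypes_per_type <= 1:
            return t
        return f"{t}/s{i % spec.subtypes_per_type + 1}"

    a = spec.ambient_fraction
    for pid, cond in patients:
        counter = 0
        for t in types:
            mu = profiles[(t, cond)] * jitter[pid]
            p_own = mu / mu.sum()
            total = mu.sum()
            for i in range(n_per):
                counter += 1
                obs_rows.append((f"{pid}_c{counter}", pid, cond, t, subtype_of(t, i)))
                truth_label.append("real")
                qc_fail.append("")
                mu_rows.append(total * ((1 - a) * p_own + a * ambient_profile))
        for kind, n_fail, frac, idx in (
            ("high_mito", spec.n_high_mito_per_patient, spec.high_mito_fraction, mito_idx),
            ("high_erythrocyte", spec.n_high_ery_per_patient, spec.high_ery_fraction, ery_idx),
        ):
            for j in range(n_fail):
                t = types[j % len(types)]
                mu = _boost_fraction(profiles[(t, cond)], idx, frac) * jitter[pid]
                p_own = mu / mu.sum()
                total = mu.sum()
                counter += 1
                obs_rows.append((f"{pid}_c{counter}", pid, cond, t, subtype_of(t, j)))
                truth_label.append("real")
                qc_fail.append(kind)
                mu_rows.append(total * ((1 - a) * p_own + a * ambient_profile))

    n_real = len(mu_rows)
    mu_mat = np.asarray(mu_rows)
    sig_l = spec.library_size_lognormal_sigma
    if sig_l > 0:
        lib = np.exp(rng.normal(0.0, sig_l, size=n_real) - 0.5 * sig_l**2)
    else:
        lib = np.ones(n_real)
    mu_mat *= lib[:, None]

    r = spec.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu_mat / r)
    counts_real = rng.poisson(lam).astype(np.float64)

    empty_rows: list[np.ndarray] = []
    lo, hi = spec.empty_droplet_umi_range
    for pid, cond in patients:
        for j in range(spec.n_empty_droplets_per_patient):
            total = int(rng.integers(lo, hi + 1))
            empty_rows.append(
                rng.multinomial(total, ambient_profile).astype(np.float64)
            )
            obs_rows.append(
                (f"{pid}_e{j + 1}", pid, cond, EMPTY_LABEL, EMPTY_LABEL)
            )
            truth_label.append(EMPTY_LABEL)
            qc_fail.append("")

    X = np.vstack([counts_real] + ([np.asarray(empty_rows)] if empty_rows else []))
    obs = pd.DataFrame(
        obs_rows, columns=["cell_id", "patient", "condition", "cell_type", "cell_subtype"]
    ).set_index("cell_id")
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))

    truth = GroundTruth(
        genes=genes,
        cell_types=types,
        ambient_profile=pd.Series(ambient_profile, index=genes, name="ambient"),
        droplet_label=pd.Series(truth_label, index=adata.obs_names, name="droplet_label"),
        qc_fail=pd.Series(qc_fail, index=adata.obs_names, name="qc_fail"),
        expected_expression={k: v.copy() for k, v in profiles.items()},
        planted_de=list(spec.planted_de),
        planted_lr=list(spec.planted_lr),
    )
    return adata, truth


def generate_lr_table(
    spec: SyntheticSpec, n_null_pairs: int, seed: int | None = None
) -> pd.DataFrame:
    """Ligand-receptor pair table: planted pairs plus random decoys.

    Decoy genes are drawn (without replacement per pair slot) from generic
    genes that take part in no planted effect and carry no marker boost, so
    decoys are exchangeable null pairs. Returns a two-column DataFrame
    (``ligand``, ``receptor``) with no duplicate rows.
    """
    if n_null_pairs < 0:
        raise ConfigurationError("n_null_pairs must be >= 0")
    spec.validate()
    genes = spec.gene_names()
    planted_genes = {p.ligand for p in spec.planted_lr} | {
        p.receptor for p in spec.planted_lr
    }
    planted_genes |= {p.gene for p in spec.planted_de}
    marker_idx = {i for idxs in _marker_assignment(spec).values() for i in idxs}
    n_special = len(spec.erythrocyte_genes) + spec.mito_gene_count
    pool = [
        g
        for i, g in enumerate(genes)
        if i >= n_special and i not in marker_idx and g not in planted_genes
    ]
    if 2 * n_null_pairs > len(pool):
        raise ConfigurationError(
            f"need {2 * n_null_pairs} non-planted genes for decoys, have {len(pool)}"
        )
    rows = [(p.ligand, p.receptor) for p in spec.planted_lr]
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    chosen = rng.choice(len(pool), size=2 * n_null_pairs, replace=False)
    for k in range(n_null_pairs):
        rows.append((pool[chosen[2 * k]], pool[chosen[2 * k + 1]]))
    table = pd.DataFrame(rows, columns=["ligand", "receptor"])
    return table.drop_duplicates(ignore_index=True)


def generate_bulk_mixtures(
    signature: pd.DataFrame,
    proportions: pd.DataFrame,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Bulk sample x gene table mixed from per-type signatures.

    ``signature`` is genes x types; ``proportions`` is samples x types and
    each row must sum to 1 (within 1e-8). Each bulk profile is the
    proportion-weighted sum of type signatures with multiplicative mean-one
    lognormal noise of scale ``noise_sd``. Deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    missing = [t for t in proportions.columns if t not in signature.columns]
    if missing:
        raise ConfigurationError(f"proportions reference unknown types: {missing}")
    sums = proportions.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > 1e-8]
    if len(bad):
        raise ConfigurationError(
            f"sample proportions must sum to 1: offenders {list(bad.index)}"
        )
    rng = np.random.default_rng(seed)
    clean = proportions.to_numpy() @ signature[proportions.columns].to_numpy().T
    if noise_sd > 0:
        clean = clean * np.exp(
            rng.normal(0.0, noise_sd, size=clean.shape) - 0.5 * noise_sd**2
        )
    return pd.DataFrame(clean, index=proportions.index, columns=signature.index)
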