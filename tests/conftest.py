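import anndata as ad
import numpy as np
import pandas as pd
import pytest

from ccatlas.synthetic import SyntheticSpec, generate_atlas


def make_adata(
    X,
    genes=None,
    patients=None,
    conditions=None,
    cell_types=None,
    cell_subtypes=None,
    cell_ids=None,
):
    """Build a small AnnData (cells x genes) with the standard obs columns."""
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    genes = list(genes) if genes is not None else [f"g{j + 1}" for j in range(g)]
    obs = pd.DataFrame(
        {
            "patient": patients if patients is not None else ["p1"] * n,
            "condition": conditions if conditions is not None else ["case"] * n,
            "cell_type": cell_types if cell_types is not None else ["t1"] * n,
        }
    )
    obs["cell_subtype"] = (
        list(cell_subtypes) if cell_subtypes is not None else obs["cell_type"]
    )
    obs.index = pd.Index(
        cell_ids if cell_ids is not None else [f"c{i + 1}" for i in range(n)],
        name="cell_id",
    )
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


@pytest.fixture(scope="session")
def default_atlas():
    """One full-size synthetic atlas shared across read-only tests."""
    spec = SyntheticSpec(seed=11)
    adata, truth = generate_atlas(spec)
    return spec, adata, truth


@pytest.fixture(scope="session")
def small_atlas():
    """A compact atlas (2 types, 2+2 patients) for pipeline-level tests."""
    spec = SyntheticSpec(
        n_genes=1300,
        n_cell_types=2,
        cells_per_type_per_patient=60,
        n_patients_case=2,
        n_patients_control=2,
        n_empty_droplets_per_patient=30,
        marker_genes_per_type=10,
        baseline_mean=3.0,
        gene_mean_lognormal_sigma=0.5,
        n_high_mito_per_patient=2,
        n_high_ery_per_patient=2,
        seed=5,
    )
    adata, truth = generate_atlas(spec)
    return spec, adata, truth
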