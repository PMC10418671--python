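import numpy as np
import pandas as pd
import pytest

from omniblock.data import FeatureTable


def make_table(
    intensities: np.ndarray,
    roles=None,
    groups=None,
    orders=None,
    assays=None,
    sample_ids=None,
    feature_ids=None,
    **sample_cols,
) -> FeatureTable:
    """Build a valid FeatureTable from an array with minimal boilerplate."""
    intensities = np.asarray(intensities, dtype=float)
    n, p = intensities.shape
    sample_ids = list(sample_ids) if sample_ids is not None else [f"s{i+1}" for i in range(n)]
    feature_ids = list(feature_ids) if feature_ids is not None else [f"f{j+1}" for j in range(p)]
    roles = list(roles) if roles is not None else ["study"] * n
    if groups is None:
        groups = [("a" if i % 2 == 0 else "b") if r == "study" else None
                  for i, r in enumerate(roles)]
    orders = list(orders) if orders is not None else list(range(1, n + 1))
    assays = list(assays) if assays is not None else ["metabolomics"] * p
    smeta = pd.DataFrame(
        {"role": roles, "injection_order": orders, "group": groups, **sample_cols},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    fmeta = pd.DataFrame(
        {"assay": assays, "annotation": feature_ids},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    inten = pd.DataFrame(intensities, index=sample_ids, columns=feature_ids)
    return FeatureTable(inten, smeta, fmeta).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_valid_table():
    r = np.random.default_rng(42)
    inten = np.exp(r.normal(5, 1, size=(8, 5)))
    roles = ["study"] * 4 + ["qc"] * 3 + ["blank"]
    return make_table(inten, roles=roles)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared by preprocessing/model tests."""
    from omniblock.simulate import SyntheticSpec, generate_table

    spec = SyntheticSpec(
        n_per_group=30,
        n_metabolite_features=40,
        n_lipid_features=30,
        n_functional_blocks=10,
        n_lipid_clusters_true=3,
        seed=7,
    )
    table, truth = generate_table(spec)
    return spec, table, truth
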