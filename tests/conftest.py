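import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tripathotype import atlas as am
from tripathotype import de, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_atlas():
    """Default synthetic atlas with its planted ground truth."""
    return synthetic.generate_atlas(synthetic.AtlasSpec(seed=0))


@pytest.fixture(scope="session")
def default_modules(default_atlas):
    """Six cell-type modules derived from the default atlas."""
    atlas_df, _ = default_atlas
    z, eligible = am.zscore_tissues(atlas_df)
    return [am.derive_module(z, t, eligible=eligible)
            for t in synthetic.CELL_TYPE_NAMES[:6]]


@pytest.fixture(scope="session")
def default_cohort(default_modules):
    """Default synthetic cohort (65 samples, 2,000 genes) with modules planted."""
    spec = synthetic.CohortSpec(seed=1)
    counts, histology, clinical, truth = synthetic.generate_cohort(spec, default_modules)
    return spec, counts, histology, clinical, truth


@pytest.fixture(scope="session")
def cohort_annotations(default_cohort):
    _, counts, _, _, truth = default_cohort
    return pd.DataFrame(
        {"pathotype": [truth.group_assignment[s] for s in counts.columns]},
        index=counts.columns,
    )


@pytest.fixture(scope="session")
def default_de_result(default_cohort, cohort_annotations):
    """Three-group DE on the default cohort (computed once per session)."""
    _, counts, _, _, _ = default_cohort
    return de.run_threeway_de(counts, cohort_annotations)


def small_count_matrix(seed=0, n_genes=50, n=12):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rng.uniform(5, 200, n_genes)[:, None], size=(n_genes, n))
    return pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{i}" for i in range(n)])
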