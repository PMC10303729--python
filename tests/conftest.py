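import numpy as np
import pandas as pd
import pytest

import hspcmeth as h

HSPC_TYPES = ["HSC", "LMPP", "CMP"]
LEUKO_GROUPS = ["granulocyte", "CD4T", "Bcell"]


@pytest.fixture(scope="session")
def subset_spec() -> h.SyntheticSpec:
    """Reference-study conditions: 3 HSPC subsets + 3 leukocyte groups,
    3 hyper + 3 hypo markers per type, strong separation, tight replicates."""
    return h.SyntheticSpec(
        n_cell_types=6,
        cell_type_names=HSPC_TYPES + LEUKO_GROUPS,
        n_background_cpgs=200,
        markers_per_type=(3, 3),
        marker_delta=0.6,
        within_type_sd=0.02,
        noise_sd=0.02,
        samples_per_type=5,
        seed=20230627,
    )


@pytest.fixture(scope="session")
def reference_data(subset_spec):
    return h.make_reference_profiles(subset_spec)


@pytest.fixture(scope="session")
def subset_atlas(reference_data) -> h.ReferenceAtlas:
    """Four-type atlas (HSC/LMPP/CMP/leukocytes) over each subset's markers."""
    beta, ann, truth = reference_data
    marker_ids = sorted(truth)
    return h.build_reference(
        beta, ann, HSPC_TYPES + ["leukocytes"], marker_ids,
        leukocyte_groups=LEUKO_GROUPS,
    )


PAN_HSPC_CPGS = ["cg17707057", "cg00164282", "cg17607231"]


@pytest.fixture(scope="session")
def pan_atlas(subset_atlas) -> h.ReferenceAtlas:
    """Subset atlas extended with pan-HSPC marker CpGs: methylated alike in
    every HSPC subset, unmethylated in leukocytes (the total-HSPC panel
    regime)."""
    pan = pd.DataFrame(
        {
            "HSC": [0.85, 0.80, 0.75],
            "LMPP": [0.85, 0.80, 0.75],
            "CMP": [0.85, 0.80, 0.75],
            "leukocytes": [0.05, 0.10, 0.08],
        },
        index=PAN_HSPC_CPGS,
    )
    return h.ReferenceAtlas(pd.concat([subset_atlas.means, pan]))


@pytest.fixture
def two_type_atlas() -> h.ReferenceAtlas:
    """Hand-written CD34+/CD34− atlas over a 3-CpG hypermethylated panel."""
    return h.ReferenceAtlas(
        pd.DataFrame(
            {
                "CD34pos": [0.85, 0.80, 0.75],
                "CD34neg": [0.05, 0.10, 0.08],
            },
            index=["cg17707057", "cg00164282", "cg17607231"],
        )
    )
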