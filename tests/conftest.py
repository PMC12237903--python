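import numpy as np
import pytest

from gutnet import CorrSpec, OtuTable, SiteDesign, generate_basis_counts, generate_multisite_study


@pytest.fixture(scope="session")
def null_table():
    """20 uncorrelated OTUs x 50 samples."""
    design = SiteDesign("null", n_otus=20, n_samples=50, depth_mean=2000)
    return generate_basis_counts(design, seed=1)


@pytest.fixture(scope="session")
def planted_table():
    """20 OTUs x 200 samples with one strong planted pair (0, 1)."""
    design = SiteDesign(
        "planted", n_otus=20, n_samples=200, depth_mean=5000,
        sigma=1.0, corr_spec=CorrSpec(pairs=[(0, 1, 0.9)]),
    )
    return generate_basis_counts(design, seed=1)


@pytest.fixture(scope="session")
def tiny_bundle():
    """3-site study, 12 OTUs x 40 samples: 1 shared + 1 specific pair per site."""
    designs = [
        SiteDesign(site, n_otus=12, n_samples=40, depth_mean=2000, sigma=1.0)
        for site in ("ileum", "cecum", "feces")
    ]
    return generate_multisite_study(
        designs,
        shared_pairs=[(0, 1, 0.8)],
        specific_pairs={"ileum": [(2, 3, 0.9)], "cecum": [(4, 5, 0.9)], "feces": [(6, 7, 0.9)]},
        seed=7,
    )


@pytest.fixture
def toy_counts():
    counts = np.array(
        [
            [5, 0, 2],
            [3, 1, 0],
            [2, 4, 4],
            [0, 5, 4],
        ]
    )
    return OtuTable(counts, otu_ids=list("ABCD"), sample_ids=["S1", "S2", "S3"])
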