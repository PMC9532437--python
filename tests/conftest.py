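import numpy as np
import pytest

from sclctools import SimConfig, generate_dataset, normalize
from sclctools.simulate import COMPARTMENTS


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic cohort (fixed seed), shared across tests."""
    return generate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_expr(default_sim):
    cm, _, _, _ = default_sim
    return normalize(cm)


def two_population_config(seed=1):
    """Malignant + normal-epithelial only, with two large planted segments
    (fold 0.5 and 1.5, 300 genes each) — the CNV recovery condition."""
    cells = {c: 0 for c in COMPARTMENTS}
    cells.update(malignant=300, normal_epithelial=300)
    return SimConfig(
        seed=seed,
        n_patients=1,
        n_chromosomes=5,
        cells_per_compartment=cells,
        cnv_segments=[(0, 1, 0, 300, 0.5), (0, 3, 50, 300, 1.5)],
        subtype_fractions={0: {"SCLC-A": 1.0}},
    )


@pytest.fixture(scope="session")
def cnv_sim():
    return generate_dataset(two_population_config(seed=1))


def segment_profile_mean(profile, truth, segment_index):
    """Mean CNV profile value per cell over one planted segment's genes."""
    genes = set(truth.cnv_segment_genes[segment_index])
    cols = np.flatnonzero(profile.gene_order["gene_id"].isin(genes).to_numpy())
    return profile.values[:, cols].mean(axis=1)
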