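import numpy as np
import pandas as pd
import pytest

from crossdiet import composition as comp
from crossdiet import simulate as sim
from crossdiet.containers import CompositionTable, CountTable


@pytest.fixture(scope="session")
def small_trial():
    """A small but structured cross-over dataset (8 dogs, 5 phyla)."""
    design = sim.TrialDesign(n_dogs_per_group=4, exclusions_per_group=(0, 0))
    truth = sim.default_ground_truth(categories=5, design=design, phi=80.0,
                                     sigma_u=0.4, depth_range=(2_000, 5_000),
                                     seed=42)
    return sim.simulate_dataset(design, truth, seed=42)


@pytest.fixture(scope="session")
def small_composition(small_trial):
    rel = comp.relative_abundance(small_trial.counts)
    return comp.adjust_zeros(rel, 1e-6)


@pytest.fixture
def otu_table():
    """Hand-built OTU table with known lineages, 3 samples."""
    counts = pd.DataFrame(
        {
            "s1": [3, 4, 10, 2, 1],
            "s2": [0, 6, 5, 5, 4],
            "s3": [1, 1, 1, 1, 16],
        },
        index=[f"OTU{i}" for i in range(1, 6)],
    )
    taxonomy = pd.Series(
        {
            "OTU1": "k__Bacteria; p__Firmicutes; f__Lachnospiraceae; g__Blautia",
            "OTU2": "k__Bacteria; p__Firmicutes; f__Lachnospiraceae; g__Roseburia",
            "OTU3": "k__Bacteria; p__Bacteroidetes; f__Prevotellaceae; g__Prevotella",
            "OTU4": "k__Bacteria; p__Bacteroidetes; f__Bacteroidaceae; g__Bacteroides",
            "OTU5": "k__Bacteria; p__Proteobacteria",  # no family label
        }
    )
    return CountTable(counts=counts, taxonomy=taxonomy)


@pytest.fixture
def simple_metadata():
    meta = pd.DataFrame(
        {
            "SampleID": ["s1", "s2", "s3"],
            "DogID": ["d1", "d1", "d2"],
            "Group": ["ACB", "ACB", "BCA"],
            "Period": ["baseline", "phase1", "baseline"],
            "Diet": ["C", "A", "C"],
        }
    )
    return meta


def make_composition(values, samples=None, categories=None) -> CompositionTable:
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(1, values.shape[0] + 1)]
    categories = categories or [f"t{i}" for i in range(1, values.shape[1] + 1)]
    return CompositionTable(
        proportions=pd.DataFrame(values, index=samples, columns=categories))
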