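import numpy as np
import pandas as pd
import pytest

from glvnet.models import GLVModel, TimeSeriesProfile
from glvnet.synthetic import sample_interaction_matrix, simulate_glv


@pytest.fixture
def two_taxon_model():
    """A simple stable two-taxon community with one commensal edge."""
    return GLVModel(
        taxa=["A", "B"],
        growth_rates=np.array([0.5, 0.4]),
        interactions=np.array([[-0.5, 0.0], [0.3, -0.8]]),
    )


@pytest.fixture
def five_taxon_model():
    return sample_interaction_matrix(
        5,
        {"mutual": 0.3, "competitive": 0.3, "commensal": 0.2, "amensal": 0.2},
        seed=7,
    )


@pytest.fixture
def dense_profile(five_taxon_model):
    """Noise-free densely sampled trajectory (normalized)."""
    x0 = np.random.default_rng(7).uniform(0.05, 0.3, 5)
    times = np.arange(0, 2.0001, 0.02)
    return simulate_glv(five_taxon_model, x0, times, noise_sd=0.0)


@pytest.fixture
def study_schedule_profile(five_taxon_model):
    """A 12-point profile on the uneven study-style sampling schedule."""
    from glvnet.synthetic import DEFAULT_TIMES

    x0 = np.random.default_rng(3).uniform(0.05, 0.3, 5)
    return simulate_glv(five_taxon_model, x0, DEFAULT_TIMES, noise_sd=0.05, seed=3)


@pytest.fixture
def lineage_table():
    """A small genus-collapsible count table with lineage strings."""
    from glvnet.models import AbundanceTable

    taxa = [
        "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; "
        "f__Streptococcaceae; g__Lactococcus; s__garvieae",
        "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; "
        "f__Streptococcaceae; g__Lactococcus; s__lactis",
        "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; "
        "o__Enterobacteriales; f__Enterobacteriaceae; g__; s__",
        "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Actinomycetales; "
        "f__Corynebacteriaceae; g__Corynebacterium; s__variabile",
    ]
    counts = pd.DataFrame(
        [[10, 20], [5, 0], [7, 3], [100, 50]],
        index=taxa,
        columns=["s1", "s2"],
    )
    meta = pd.DataFrame({"time": [1.0, 11.0]}, index=["s1", "s2"])
    return AbundanceTable(counts=counts, metadata=meta)
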