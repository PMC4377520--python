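"""Shared fixtures: synthetic datasets and trained models at several scales."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nolscan.genome_io import GeneModel, extract_boundaries
from nolscan.nol_model import train
from nolscan.boundary_profiles import build_windows, call_minima, dedup_calls
from nolscan.synthetic import SyntheticSpec, make_training_set, simulate_genome

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_genes=60, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return simulate_genome(small_spec)


@pytest.fixture(scope="session")
def small_model(small_spec):
    pos, neg = make_training_set(small_spec)
    return train(pos, neg, seed=small_spec.seed)


@pytest.fixture(scope="session")
def small_calls(small_dataset, small_model):
    sites = extract_boundaries(small_dataset.models)
    windows = build_windows(small_dataset.genome, sites, small_model)
    return dedup_calls(call_minima(windows))


@pytest.fixture(scope="session")
def default_run():
    """The full-scale study-condition run: default spec, seed 1.

    Shared by the acceptance checks for feature recovery, enrichment and
    genomic-characteristic statistics.
    """
    spec = SyntheticSpec(seed=1)
    ds = simulate_genome(spec)
    pos, neg = make_training_set(spec)
    model = train(pos, neg, seed=spec.seed)
    sites = extract_boundaries(ds.models)
    windows = build_windows(ds.genome, sites, model)
    calls = dedup_calls(call_minima(windows))
    return {"spec": spec, "dataset": ds, "model": model,
            "sites": sites, "calls": calls}


@pytest.fixture
def toy_models():
    """Hand-written gene models on a 1 kb toy chromosome."""
    return [
        GeneModel(name="tx1", gene="gA", chrom="chrT", strand="+",
                  exon_starts=(100, 300, 500), exon_ends=(200, 400, 600)),
        GeneModel(name="tx2", gene="gB", chrom="chrT", strand="-",
                  exon_starts=(600, 800), exon_ends=(700, 900)),
        GeneModel(name="tx3", gene="gC", chrom="chrT", strand="+",
                  exon_starts=(50,), exon_ends=(90,)),
    ]


@pytest.fixture
def toy_genome(toy_models):
    rng = np.random.default_rng(42)
    seq = rng.choice(list("ACGT"), size=1000)
    return {"chrT": "".join(seq)}
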