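import numpy as np
import pytest

from mpralocus import simgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_reference():
    """A 2 kb random reference used by association-level tests."""
    return simgen.random_reference(2000, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_simulation(small_reference):
    """A small error-free LS-MPRA simulation with ground truth.

    Read length exceeds the fragment size so association mate 2 carries
    each full fragment and the consensus interval is exact.
    """
    spec = simgen.SimSpec(
        seed=11,
        n_fragments=150,
        fragment_size_range=(100, 200),
        read_length=250,
        association_reads_per_barcode=3,
        cdna_depth=20_000,
    )
    rng = np.random.default_rng(spec.seed)
    model = simgen.ActivityModel(regions=[(800, 1100, 8.0)])
    fragments = simgen.fragment_reference(small_reference, spec, rng)
    association = simgen.assign_barcodes(fragments, spec, rng)
    counts = simgen.simulate_expression(association, model, spec.cdna_depth, rng)
    pairs, cdna = simgen.emit_reads(association, counts, small_reference, spec, rng)
    return {
        "spec": spec,
        "model": model,
        "reference": small_reference,
        "fragments": fragments,
        "association": association,
        "counts": counts,
        "assoc_pairs": pairs,
        "cdna_reads": cdna,
    }
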