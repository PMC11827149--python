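import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mprakit import BarcodeCountTable, SimulationSpec, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_counts(records) -> BarcodeCountTable:
    """records: iterable of (replicate, barcode, oligo, dna, rna)."""
    df = pd.DataFrame(records, columns=["replicate", "barcode", "oligo",
                                        "dna_count", "rna_count"])
    return BarcodeCountTable.from_frame(df)


def grid_counts(oligo_barcodes: dict, reps=("r1", "r2", "r3"), dna=10, rna=10):
    """Full (replicate x barcode) grid with constant counts.

    oligo_barcodes: mapping oligo -> list of barcode names.
    """
    recs = []
    for oligo, bcs in oligo_barcodes.items():
        for bc in bcs:
            for r in reps:
                recs.append((r, bc, oligo, dna, rna))
    return make_counts(recs)


@pytest.fixture(scope="session")
def small_sim():
    """200-variant simulated dataset shared by unit tests."""
    spec = SimulationSpec(n_variants=200, seed=7)
    counts, truth, vmap = simulate_dataset(spec)
    return counts, truth, vmap


@pytest.fixture
def rng():
    return np.random.default_rng(42)
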