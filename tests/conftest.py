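import numpy as np
import pandas as pd
import pytest

from barcodekit.io import Dataset, SequenceRecord


def make_dataset(entries):
    """Build a Dataset from (id, sequence, species[, genus, family, order]) tuples."""
    records = []
    for e in entries:
        sid, seq, sp = e[0], e[1], e[2]
        genus = e[3] if len(e) > 3 else sp.split("_")[0] + "_gen"
        family = e[4] if len(e) > 4 else "fam1"
        order = e[5] if len(e) > 5 else "ord1"
        records.append(SequenceRecord(sid, seq, sp, genus, family, order))
    return Dataset(records=records, alignment_length=len(entries[0][1]))


@pytest.fixture
def two_species_dataset():
    """Two 2-specimen species separated by many substitutions."""
    base = "ACGT" * 10
    far = "GCGT" * 4 + "ACGT" * 6  # 4 transitions, ~10%
    return make_dataset(
        [
            ("a1", base, "sp_a", "gen_a"),
            ("a2", base[:-1] + "C", "sp_a", "gen_a"),
            ("b1", far, "sp_b", "gen_b"),
            ("b2", far[:-1] + "C", "sp_b", "gen_b"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
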