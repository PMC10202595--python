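from __future__ import annotations

import pytest

from sagrad import ReadRecord, SimConfig


@pytest.fixture
def sim_config():
    """Factory for small, fast simulation configs; error sources off by default."""

    def make(**overrides) -> SimConfig:
        params = dict(
            n_populations=1,
            n_individuals_per_pop=1,
            n_sag_replicates=1,
            n_bulk_replicates=0,
            n_loci=60,
            locus_length=600,
            het_rate=0.1,
            divergence=0.0,
            mda_sigma=0.0,
            dropout_prob=0.0,
            contamination_frac=0.0,
            pcr_dup_rate=0.0,
            reads_per_sample=1500,
            seq_error_rate=0.0,
            seed=0,
        )
        params.update(overrides)
        return SimConfig(**params)

    return make


@pytest.fixture
def make_read():
    """Factory for hand-built read pairs with all-Q37 qualities by default."""

    def make(
        seq1: str,
        seq2: str = "ACGT" * 10,
        qual1: str | None = None,
        qual2: str | None = None,
        read_id: str = "r",
        insert: int | None = 400,
    ) -> ReadRecord:
        q = chr(37 + 33)
        return ReadRecord(
            read_id,
            seq1,
            seq2,
            qual1 if qual1 is not None else q * len(seq1),
            qual2 if qual2 is not None else q * len(seq2),
            insert=insert,
        )

    return make
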