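import numpy as np
import pytest

from dmmrkit import io_formats, synthetic_data


@pytest.fixture(scope="session")
def shape_table():
    return synthetic_data.gen_shape_table(3, prot_shift=-4.0, roll_shift=3.0)


@pytest.fixture(scope="session")
def small_genome():
    return {"chrS": synthetic_data.gen_reference_sequence(20_000, 0.5, 1)}


@pytest.fixture(scope="session")
def cohort_records():
    return io_formats.load_cohort_fixture()


@pytest.fixture(scope="session")
def variant_records():
    return io_formats.load_variant_fixture()


def reverse_complement_genome(genome):
    """Mirror a genome dict for strand-collapse invariance checks."""
    from dmmrkit.sbs96 import reverse_complement

    return {chrom: reverse_complement(seq) for chrom, seq in genome.items()}


def reverse_complement_variants(records, genome):
    from dmmrkit.io_formats import VariantRecord
    from dmmrkit.sbs96 import COMPLEMENT

    out = []
    for rec in records:
        length = len(genome[rec.chrom])
        out.append(
            VariantRecord(
                sample=rec.sample,
                chrom=rec.chrom,
                pos=length - rec.pos + 1,
                ref=COMPLEMENT[rec.ref],
                alt=COMPLEMENT[rec.alt],
                variant_class=rec.variant_class,
            )
        )
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_319)
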