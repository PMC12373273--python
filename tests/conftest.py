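import pytest

from g4var.sequences import SequenceStore, load_sequences
from g4var.synth import FixtureSpec, make_genome, make_variants

# 25-nt G4 whose single full window scores 38/25 = 1.52, and its G>A
# mutant at offset 23 (1-based), scoring 27/25 = 1.08
WT_SEQ = "GGGTGGCGGAGGACGGTCGACGGGG"
MUT_SEQ = "GGGTGGCGGAGGACGGTCGACGAGG"

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@pytest.fixture
def worked_store():
    return SequenceStore({"g4": WT_SEQ})


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Default synthetic dataset: genome, plants, VCF/MAF, truth table."""
    out = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(seed=42, n_variants=60, indel_fraction=0.2)
    fasta, plants = make_genome(spec, out)
    store = load_sequences(fasta)
    sequences = {n: store.sequence(n) for n in store.names}
    vcf, maf, truth = make_variants(spec, plants, sequences, out)
    return {
        "spec": spec,
        "fasta": fasta,
        "plants": plants,
        "store": store,
        "vcf": vcf,
        "maf": maf,
        "truth": truth,
        "dir": out,
    }
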