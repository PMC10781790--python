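import numpy as np
import pytest

from evsmall.reference import ReferenceBundle, SncRnaReference
from evsmall.synthetic import SyntheticConfig, generate_reference_bundle


@pytest.fixture(scope="session")
def toy_config():
    return SyntheticConfig(
        seed=1, n_mirna=20, n_other_per_class=5, n_healthy=6, n_irbd=6, n_pd=6
    )


@pytest.fixture(scope="session")
def toy_bundle(toy_config):
    return generate_reference_bundle(toy_config)


@pytest.fixture()
def mirna_ref():
    """Hand-built miRNA anchored in a precursor with known flanks.

    mature = precursor[5:27] (22 nt), 5 nt upstream, 8 nt downstream.
    """
    precursor = "GGGCC" + "ACGTACGTTGCAGGCACTCAAT" + "TTGCAGGA"
    return SncRnaReference(
        feature_id="miR-toy",
        rna_class="miRNA",
        sequence=precursor[5:27],
        precursor_sequence=precursor,
        mature_start=5,
        mature_end=27,
    )


@pytest.fixture()
def small_bundle(mirna_ref):
    bundle = ReferenceBundle()
    bundle.add(mirna_ref)
    bundle.add(
        SncRnaReference(
            feature_id="ysRNA-a",
            rna_class="ysRNA",
            sequence="TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAA",
        )
    )
    bundle.add(
        SncRnaReference(
            feature_id="ysRNA-b",
            rna_class="ysRNA",
            sequence="AAAATTTTGGGGCCCCAAAATTTTGGGG",
        )
    )
    bundle.add(
        SncRnaReference(
            feature_id="tsRNA-a",
            rna_class="tsRNA",
            sequence="CACACACACACACACACACACACACACACACA",
        )
    )
    return bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
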