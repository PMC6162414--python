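import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def let7a():
    from compete_scan.mirna_scan import MiRNA

    return MiRNA("let-7a", "UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture
def gc_motif():
    """Two-column consensus 'GC' motif with no pseudocount (exactly 1/16
    of background dinucleotides attain the maximal score)."""
    from compete_scan.rbp_scan import MotifModel

    return MotifModel(
        "GC",
        np.array([[0.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 0.0]]),
        pseudocount=0.0,
    )


def random_rna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
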