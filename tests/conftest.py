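import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from elavscan.motifs import MotifSet, t_normalize

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def naive_scan(seq: str, motifs: MotifSet):
    """Independent every-offset oracle for the exact-match scanner."""
    norm = t_normalize(seq)
    hits = []
    for m in motifs:
        p = m.pattern
        for i in range(len(norm) - len(p) + 1):
            if norm[i:i + len(p)] == p:
                hits.append((i, i + len(p), m.motif_id))
    return sorted(hits, key=lambda h: (h[0], h[2]))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_sequence():
    def make(rng, length, alphabet="ACGTUacgtu", au_rich=False):
        letters = list(alphabet)
        if au_rich:
            probs = np.array([0.35, 0.05, 0.05, 0.3, 0.05, 0.1, 0.02, 0.02, 0.05, 0.01])
            probs = probs / probs.sum()
            return "".join(rng.choice(letters, size=length, p=probs))
        return "".join(rng.choice(letters, size=length))

    return make
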