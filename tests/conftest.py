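import numpy as np
import pytest

from lnchomex.fixtures import FixtureSpec, make_motif_library


@pytest.fixture(scope="session")
def spec() -> FixtureSpec:
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def library(spec):
    return make_motif_library(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def point_mass_pwm(consensus: str, motif_id: str = "PM", hi: float = 0.997):
    """A near-deterministic PWM whose only credible match is its consensus."""
    from lnchomex.motifs import BASES, Pwm

    mat = np.full((len(consensus), 4), (1.0 - hi) / 3.0)
    for i, b in enumerate(consensus):
        mat[i, BASES.index(b)] = hi
    mat /= mat.sum(axis=1, keepdims=True)
    return Pwm(motif_id, motif_id, "test", mat)


def brute_force_mpss(sim: np.ndarray) -> float:
    """Exhaustive max over all monotone (non-crossing) block matchings."""
    na, nb = sim.shape
    best = 0.0

    def rec(i: int, j: int, acc: float) -> None:
        nonlocal best
        if acc > best:
            best = acc
        for ii in range(i, na):
            for jj in range(j, nb):
                if sim[ii, jj] > 0:
                    rec(ii + 1, jj + 1, acc + sim[ii, jj])

    rec(0, 0, 0.0)
    return best


def random_profile_pair(rng, n_classes=6, max_blocks=7, length=1000, max_count=4):
    """Small random block-profile pair for DP-vs-oracle checks."""
    from lnchomex.motifs import BlockProfile, MotifBlock

    def one(seq_id):
        n = int(rng.integers(1, max_blocks + 1))
        centers = np.sort(rng.uniform(20, length - 20, size=n))
        blocks = []
        for c in centers:
            k = int(rng.integers(1, 4))
            classes = rng.choice(n_classes, size=min(k, n_classes), replace=False)
            counts = {f"C{q}": int(rng.integers(1, max_count + 1)) for q in classes}
            blocks.append(MotifBlock(seq_id, int(c) - 5, int(c) + 5, float(c), counts))
        return BlockProfile(seq_id, length, tuple(blocks))

    return one("a"), one("b")
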