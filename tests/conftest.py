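import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import motuforge as mf

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def toy_library():
    """Three species, two sequences each, with an obvious barcode gap."""
    base = "ACGT" * 25
    def mutate(seq, positions, bases):
        s = list(seq)
        for p, b in zip(positions, bases):
            s[p] = b
        return "".join(s)

    records = [
        mf.SequenceRecord("a1", base, "alpha", "genA", "famA", "ord1", "trawl", "S1"),
        mf.SequenceRecord("a2", mutate(base, [3], ["A"]), "alpha", "genA", "famA", "ord1", "trawl", "S1"),
        mf.SequenceRecord("b1", mutate(base, range(10, 20), "CCCCCCCCCC"), "beta", "genA", "famA", "ord1", "market", "S2"),
        mf.SequenceRecord("b2", mutate(base, list(range(10, 20)) + [30], "CCCCCCCCCCA"), "beta", "genA", "famA", "ord1", "market", "S2"),
        mf.SequenceRecord("c1", mutate(base, range(40, 70), "G" * 30), "gamma", "genB", "famA", "ord1", "mined", "S3"),
        mf.SequenceRecord("c2", mutate(base, list(range(40, 70)) + [90], "G" * 30 + "C"), "gamma", "genB", "famA", "ord1", "mined", "S3"),
    ]
    return mf.ReferenceLibrary(records)


@pytest.fixture(scope="session")
def easy_sim():
    """One easy-preset simulated library with truth (seed 2)."""
    return mf.simulate_preset("easy", 2)


def brute_force_k2p(seq_a: str, seq_b: str):
    """Independent per-pair K2P oracle: plain python character scan."""
    import math

    purines = {"A", "G"}
    pyrimidines = {"C", "T"}
    good = purines | pyrimidines
    ts = tv = m = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in good or y not in good:
            continue
        m += 1
        if x == y:
            continue
        if (x in purines) == (y in purines):
            ts += 1
        else:
            tv += 1
    if m == 0:
        return None
    p, q = ts / m, tv / m
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
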