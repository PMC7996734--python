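import numpy as np
import pytest

from alikin import (
    Alignment,
    CovarianceParams,
    SecondaryStructure,
    ToyBackend,
    parse_dotbracket,
)


@pytest.fixture(scope="session")
def toy():
    return ToyBackend()


@pytest.fixture(scope="session")
def lam0():
    """Covariance params with the covariance term switched off."""
    return CovarianceParams(lam=0.0)


@pytest.fixture(scope="session")
def hairpin_aln():
    """Single-row alignment folding into one hairpin."""
    return Alignment.from_rows(["GGGAAACCC"])


@pytest.fixture(scope="session")
def bistable12():
    """12-nt single row with two mutually exclusive single-stack hairpins."""
    aln = Alignment.from_rows(["GGAAACCAAAGG"])
    a = parse_dotbracket("((...)).....")
    b = parse_dotbracket(".....((...))")
    return aln, a, b


@pytest.fixture(scope="session")
def compensatory2():
    """Two-row alignment whose middle pair covaries (G-C vs C-G)."""
    return Alignment.from_rows(["GGGAAACCC", "GCGAAACGC"])


def random_structure(rng: np.random.Generator, length: int, tries: int = 30) -> SecondaryStructure:
    """A random valid structure (hairpins >= 3) by rejection sampling."""
    pairs: set[tuple[int, int]] = set()
    for _ in range(tries):
        i = int(rng.integers(1, length))
        j = int(rng.integers(1, length + 1))
        if j - i < 4:
            continue
        try:
            SecondaryStructure.make(length, pairs | {(i, j)}, min_hairpin=3)
        except Exception:
            continue
        pairs.add((i, j))
    return SecondaryStructure.make(length, pairs, min_hairpin=3)
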