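import numpy as np
import pytest

from varlap.profiles import GeneStudyProfile


@pytest.fixture
def two_position_profile() -> GeneStudyProfile:
    """Two mutated positions with case counts 3 and 1; the 3-case position matched."""
    return GeneStudyProfile(
        gene="TP53",
        study_id="SKCM",
        L=400,
        case_counts={10: 3, 20: 1},
        disease_positions={10: {"D"}},
        matched_positions={10},
    )


def random_profile(rng: np.random.Generator, max_n: int = 8) -> GeneStudyProfile:
    """A random small profile with a random matched subset (for oracle checks)."""
    n = int(rng.integers(1, max_n + 1))
    positions = (rng.choice(2000, size=n, replace=False) + 1).tolist()
    counts = rng.integers(1, 6, size=n)
    m = int(rng.integers(0, n + 1))
    matched = set(rng.choice(positions, size=m, replace=False).tolist())
    return GeneStudyProfile(
        gene=f"R{rng.integers(1e6):06d}",
        study_id="SIM",
        L=2000,
        case_counts={int(p): int(c) for p, c in zip(positions, counts)},
        disease_positions={p: {"A"} for p in matched},
        matched_positions=matched,
    )
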