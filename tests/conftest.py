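import numpy as np
import pytest

from nonotet.core import PipelineConfig
from nonotet.simulate import SimulationConfig, simulate_all, simulate_study


def small_sim_config(**overrides) -> SimulationConfig:
    """A scaled-down study used by most tests (fast, same structure)."""
    kwargs = dict(
        n_chroms=2, chrom_len_bp=6_000_000, n_genes=400,
        n_dep_up=40, n_dep_down=24, n_null_up=32, n_null_down=24,
        seed=7,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_sim_config())


@pytest.fixture(scope="session")
def default_study():
    """Full study-condition simulation (5000 genes, planted 500/300)."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle") / "sim"
    simulate_all(small_sim_config(), out)
    return out


@pytest.fixture()
def cfg():
    return PipelineConfig()


def random_intervals(rng: np.random.Generator, n: int, chroms=("chrA", "chrB"),
                     span: int = 100_000, max_len: int = 2_000):
    """Random raw (chrom, start, end) triples for oracle comparisons."""
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        out.append((chrom, start, start + length))
    return out


def brute_force_overlap_mask(a, b):
    """O(n*m) all-pairs oracle: does each interval of a hit any of b."""
    mask = np.zeros(len(a), dtype=bool)
    for i, (ca, sa, ea) in enumerate(a):
        for cb, sb, eb in b:
            if ca == cb and sa < eb and sb < ea:
                mask[i] = True
                break
    return mask
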