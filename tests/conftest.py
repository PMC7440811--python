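import pytest

from dtecult import RunConfig

# Published whole-community cultivation statistics for the 17 coastal
# experiments: (site, n_wells, positive_wells, inoculum_lambda,
# printed V %, printed ASE %).
TABLE1_ROWS = [
    ("CJ", 460, 15, 1.27, 2.6, 0.67),
    ("ARD", 460, 1, 1.5, 0.1, 0.15),
    ("JLB", 460, 61, 1.96, 7.3, 0.93),
    ("FWC", 460, 301, 2.0, 53.1, 3.2),
    ("LKB", 460, 15, 1.8, 1.8, 0.48),
    ("Tbon2", 460, 41, 1.56, 6.0, 0.93),
    ("CJ2", 460, 61, 2.0, 7.1, 0.91),
    ("FWC2", 460, 403, 2.0, 104.4, 6.2),
    ("ARD2c", 460, 7, 2.0, 0.8, 0.29),
    ("JLB2c", 460, 103, 2.0, 12.7, 1.25),
    ("LKB2", 460, 39, 2.0, 4.4, 0.71),
    ("Tbon3", 460, 78, 2.0, 9.3, 1.05),
    ("CJ3", 460, 69, 2.0, 8.1, 0.98),
    ("FWC3", 460, 27, 2.0, 3.0, 0.58),
    ("ARD3", 460, 58, 2.0, 6.7, 0.89),
    ("JLB3", 460, 146, 2.0, 19.1, 1.59),
    ("LKB3", 460, 38, 2.0, 4.3, 0.70),
]


@pytest.fixture
def cfg() -> RunConfig:
    """Study-condition settings with the suite's fixed seed."""

    return RunConfig(rng_seed=42)


@pytest.fixture
def quick_cfg() -> RunConfig:
    """Reduced bootstrap count for tests that only need rough summaries."""

    return RunConfig(rng_seed=42, n_bootstraps=999)
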