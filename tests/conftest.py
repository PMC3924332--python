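import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from famfinder import FixtureSpec, PipelineConfig, make_family, plant_genome, run
from famfinder.hmm import AA, FamilyAlignment, build_profile

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_alignment() -> FamilyAlignment:
    """Small gappy alignment exercising match/insert/delete columns."""
    return FamilyAlignment(
        "tiny",
        [
            ("a", "AC-DA"),
            ("b", "ACGDA"),
            ("c", "AC-DC"),
            ("d", "A-GDA"),
        ],
    )


@pytest.fixture(scope="session")
def tiny_profile(tiny_alignment):
    return build_profile(tiny_alignment)


@pytest.fixture(scope="session")
def family40() -> FamilyAlignment:
    return make_family(n_members=40, length=60, conservation=0.85, seed=11)


@pytest.fixture(scope="session")
def calibrated_profile(family40):
    from famfinder.hmm import calibrate

    prof = build_profile(family40)
    calibrate(prof, decoy_n=1000, decoy_len=40, seed=3)
    return prof


@pytest.fixture(scope="session")
def small_truth():
    """A small planted-gene fixture shared by fast integration tests."""
    return plant_genome(
        FixtureSpec(
            seed=5,
            genome_length=40_000,
            n_single_exon=3,
            n_two_exon=3,
            n_pseudogene=2,
        )
    )


@pytest.fixture(scope="session")
def small_run(small_truth):
    cfg = PipelineConfig(seed=5, decoy_n=1000)
    return run([small_truth.genome], [small_truth.family], cfg=cfg)


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, n))
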