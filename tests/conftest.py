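import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from umivar import AlleleSpec, Edit, ErrorModel, PopulationSpec, UMIDesign

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# a realistic 20-nt universal amplification handle (TruSeq read-1 tail)
UNIVERSAL = "ACACGACGCTCTTCCGATCT"
PATTERN = "NNNNTGNNNN"


def make_ref(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), length))


def make_design(ref: str) -> UMIDesign:
    return UMIDesign(UNIVERSAL, PATTERN, ref[:20])


def spikein_spec(
    ref: str,
    frequency: float,
    n_molecules: int,
    platform: str = "nanopore",
    seed: int = 0,
    snv_pos: int = 100,
    error_model: ErrorModel | None = None,
) -> tuple[PopulationSpec, dict]:
    """Population spec for a knock-in SNV spike-in at a preset frequency,
    plus the target-variant descriptor for classification."""
    alt = "T" if ref[snv_pos] != "T" else "A"
    spec = PopulationSpec(
        reference=ref,
        alleles=[
            AlleleSpec("wt", 1.0 - frequency),
            AlleleSpec("knockin", frequency, [Edit("snv", snv_pos, alt)]),
        ],
        n_molecules=n_molecules,
        umi_design=make_design(ref),
        error_model=error_model or ErrorModel.for_platform(platform),
        platform=platform,
        seed=seed,
    )
    return spec, {"kind": "snv", "pos": snv_pos, "alt": alt}


@pytest.fixture(scope="session")
def ref168() -> str:
    return make_ref(168, seed=7)


@pytest.fixture(scope="session")
def ref2k() -> str:
    return make_ref(2000, seed=11)


@pytest.fixture()
def design168(ref168) -> UMIDesign:
    return make_design(ref168)
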