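import numpy as np
import pytest

from edcscan.synthetic_data import (
    FamilySpec,
    LocusScenario,
    RepeatSpec,
    build_locus,
)


@pytest.fixture(scope="session")
def mini_scenario() -> LocusScenario:
    """A small four-gene locus exercising both strands, both disruption
    types and the two-coding-exon (SFTP) architecture."""
    return LocusScenario(
        name="mini", seed=7, species=("sp1",),
        families=(
            FamilySpec("SEDC01", "SEDC", "GS", (120, 160)),
            FamilySpec("SEDC02", "SEDC", "QE", (120, 160), strand="-",
                       disruption="premature_stop"),
            FamilySpec("SFTP1", "SFTP", "GSCP", repeat=RepeatSpec(10, 40, 0.1)),
            FamilySpec("SEDC03", "SEDC", "PCQ", (120, 160),
                       disruption="frameshift"),
        ),
        intergenic_mean=2000, intergenic_sd=400, intergenic_min=300,
    )


@pytest.fixture(scope="session")
def mini_truth(mini_scenario):
    return build_locus(mini_scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
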