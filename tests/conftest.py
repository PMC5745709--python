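import numpy as np
import pytest

from mitodrl.drl_simulator import make_reference_genome, simulate_aneides_scenario


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reference_genome():
    return make_reference_genome(seed=1)


@pytest.fixture(scope="session")
def aneides_sim():
    return simulate_aneides_scenario(seed=11)


# the study's tree topology: four outgroup taxa, A. aeneus sister to the
# rest, the montane species sister to the coastal clade, and four sampled
# individuals of that montane species (two per observed gene order)
STUDY_NEWICK = (
    "((Desmognathus_fuscus,Plethodon_elongatus,Ensatina_eschscholtzii,"
    "Hydromantes_brunus),(aeneus,((hardii_RAC20,hardii_RAC25,hardii_RAC42,"
    "hardii_RAC54),(lugubris,(flavipunctatus,(ferreus,vagrans))))));"
)

OUTGROUP_TIPS = (
    "Desmognathus_fuscus",
    "Plethodon_elongatus",
    "Ensatina_eschscholtzii",
    "Hydromantes_brunus",
)


def study_tip_states() -> dict[str, str]:
    states = {t: "typical_vertebrate" for t in OUTGROUP_TIPS}
    for t in (
        "aeneus", "lugubris", "flavipunctatus", "ferreus", "vagrans",
        "hardii_RAC42", "hardii_RAC54",
    ):
        states[t] = "aneides_order"
    states["hardii_RAC20"] = "hardii_duplicated"
    states["hardii_RAC25"] = "hardii_duplicated"
    return states
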