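import numpy as np
import pytest

from mappkit.identification_filter import ConfidenceTier
from mappkit.peptide_mapping import MappedPeptide
from mappkit.psm_io import PSMRecord
from mappkit.sequence_model import CdrInterval, TherapeuticChain, TherapeuticMolecule
from mappkit.synthetic_data import SimulationConfig, simulate_panel

_AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))


@pytest.fixture(scope="session")
def toy_molecule() -> TherapeuticMolecule:
    """Small hand-made molecule: HC 120 aa / LC 107 aa, 3 CDRs each."""
    rng = np.random.default_rng(1234)
    hc_seq = random_protein(rng, 120)
    lc_seq = random_protein(rng, 107)
    hc = TherapeuticChain(
        "HC",
        hc_seq,
        [
            CdrInterval("HC", "HC CDR1", 26, 33),
            CdrInterval("HC", "HC CDR2", 51, 58),
            CdrInterval("HC", "HC CDR3", 97, 108),
        ],
    )
    lc = TherapeuticChain(
        "LC",
        lc_seq,
        [
            CdrInterval("LC", "LC CDR1", 24, 34),
            CdrInterval("LC", "LC CDR2", 50, 56),
            CdrInterval("LC", "LC CDR3", 89, 97),
        ],
    )
    return TherapeuticMolecule("toy-mab", hc, lc, ada_rate_text="5-26%")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_donors=3,
        background_peptides=300,
        n_background_proteins=30,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config)


@pytest.fixture(scope="session")
def mapped_factory(toy_molecule):
    """Build MappedPeptide objects for arbitrary intervals on the toy chains."""

    def make(
        intervals,
        chain_id="HC",
        donor="D1",
        sample="D1_r1",
        tier=ConfidenceTier.high,
        mods=None,
    ):
        chain = toy_molecule.chain(chain_id)
        out = []
        for start, end in intervals:
            peptide = chain.region(start, end)
            rec = PSMRecord(
                sample_id=sample,
                donor_id=donor,
                day="1",
                analyst="A",
                peptide=peptide,
                charge=2,
                xcorr=3.0 if tier == ConfidenceTier.high else 2.1,
            )
            out.append(
                MappedPeptide(
                    record=rec,
                    chain_id=chain_id,
                    start=start,
                    end=end,
                    tier=tier,
                    mods=list(mods) if mods else [],
                )
            )
        return out

    return make
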