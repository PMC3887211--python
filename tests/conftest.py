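import numpy as np
import pytest
from hypothesis import settings

from autometh import METHYL, ModifiedPeptide

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: tryptic peptide spanning the automethylated cysteine (position 4).
GIGCYMFR = "GIGCYMFR"
#: the Cys->Ser variant of the same peptide.
GIGSYMFR = "GIGSYMFR"

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def methylated_peptide() -> ModifiedPeptide:
    return ModifiedPeptide(GIGCYMFR, ((4, METHYL),))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RESIDUES), size=length))
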