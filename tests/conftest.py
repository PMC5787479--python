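import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from missingprot import ReferenceDB, ReferenceProtein

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# Tryptic building blocks: each ends in K or R with no internal cleavage site,
# so concatenations have fully predictable digests.
PEP_SHARED_ISO = "AAAAETK"   # shared by both isoforms of gene GA
PEP_A1 = "CCCDDDK"
PEP_A2 = "EEEFFFR"
PEP_B1 = "GGGHHHK"
PEP_B2 = "MMMNNNR"


@pytest.fixture
def isoform_db() -> ReferenceDB:
    """Two isoforms of one gene plus an unrelated single-isoform gene."""
    return ReferenceDB(
        [
            ReferenceProtein("A1", PEP_SHARED_ISO + PEP_A1, gene="GA", chromosome="1"),
            ReferenceProtein("A2", PEP_SHARED_ISO + PEP_A2, gene="GA", chromosome="1"),
            ReferenceProtein("B", PEP_B1 + PEP_B2, gene="GB", chromosome="2"),
        ]
    )


def random_protein_db(rng: np.random.Generator, n: int, length: int = 400) -> ReferenceDB:
    """Random toy proteome with tryptic-friendly residue frequencies."""
    alphabet = np.array(list("ACDEFGHILMNPQSTVWY" + "KR"))
    probs = np.array([0.89 / 18] * 18 + [0.055, 0.055])
    proteins = []
    for i in range(n):
        seq = "".join(rng.choice(alphabet, size=length, p=probs))
        proteins.append(
            ReferenceProtein(f"T{i:04d}", seq, gene=f"GT{i:04d}", chromosome="1")
        )
    return ReferenceDB(proteins)
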