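import numpy as np
import pytest

from oligoscreen.connectivity import PerturbationProfile
from oligoscreen.oligoscore import CurationTable
from oligoscreen.signatures import SignedGeneSet


def make_set(entries, name="q"):
    return SignedGeneSet(name=name, entries=entries)


@pytest.fixture
def fig_style_curation():
    """Curation entries mirroring the demo resource's flagship rows."""
    return CurationTable(
        entries={
            ("OLIG2", "specification"): 3,
            ("OLIG2", "differentiation"): 2,
            ("G1", "survival"): -2,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_signed_set(rng, genes, name="q"):
    signs = rng.choice([1, -1], size=len(genes))
    return SignedGeneSet(name=name, entries={g: int(s) for g, s in zip(genes, signs)})


def random_profile(rng, genes, pid="p", kind="compound"):
    values = rng.normal(0, 1, size=len(genes))
    return PerturbationProfile(
        id=pid, kind=kind, regulation={g: float(v) for g, v in zip(genes, values)}
    )
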