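import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sangerbarcode.taxonomy import Lineage, ReferenceLibrary, ReferenceRecord

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def make_lineage(*names: str) -> Lineage:
    """Pad a partial lineage out to a full kingdom..terminal chain."""
    base = ("Animalia", "Arthropoda", "Insecta", "Hymenoptera", "Formicidae")
    return Lineage(base[: 7 - len(names)] + tuple(names))


@pytest.fixture
def ant_lineages():
    return {
        "tetramorium": make_lineage("Tetramorium", "Tetramorium caespitum"),
        "monomorium_viride": make_lineage("Monomorium", "Monomorium viride"),
        "monomorium_minimum": make_lineage("Monomorium", "Monomorium minimum"),
        "gnaphosa": Lineage(
            ("Animalia", "Arthropoda", "Arachnida", "Araneae", "Gnaphosidae",
             "Gnaphosa", "Gnaphosa muscorum")
        ),
    }


def make_library(entries) -> ReferenceLibrary:
    """entries: iterable of (ref_id, marker, sequence, lineage)."""
    return ReferenceLibrary(
        [ReferenceRecord(rid, marker, seq, lin) for rid, marker, seq, lin in entries]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20140714)
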