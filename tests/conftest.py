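import pytest
from hypothesis import settings

from pubclass.io import DomainHit, ProteinRecord, load_barley_catalog

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


@pytest.fixture(scope="session")
def barley_catalog():
    return load_barley_catalog()


def make_protein(pid="P1", length=600, hits=()):
    """Shorthand: hits as (label, start, end) triples."""
    return ProteinRecord(id=pid, length_aa=length,
                         domains=tuple(DomainHit(l, s, e) for l, s, e in hits))
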