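import pytest

from redoxome.io import PlexDesign, PlexEntry, ProteinDb


@pytest.fixture
def tiny_db() -> ProteinDb:
    # P1: Cys at 8 and 30; P2: Cys at 5
    return ProteinDb(
        {
            "P1": "MKLVNRA" + "C" + "GDEFHIKLMNPQRSTVWY" + "AKR" + "C" + "GDEFHIKLM",
            "P2": "AKRW" + "C" + "LMNPQRSTVWYADEF",
        }
    )


@pytest.fixture
def paired_design() -> PlexDesign:
    """2 control + 2 depleted samples, both fractions each, one 16-plex."""
    entries = []
    channels = iter(
        ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N"]
    )
    for sample, group in [
        ("c1", "control"),
        ("c2", "control"),
        ("d1", "depleted"),
        ("d2", "depleted"),
    ]:
        entries.append(PlexEntry(next(channels), sample, group, "oxidized"))
        entries.append(PlexEntry(next(channels), sample, group, "total"))
    return PlexDesign("plex1", entries)
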