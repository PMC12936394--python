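import numpy as np
import pytest

from nicrosize.data_io import DatedTree, OccurrenceRecord


@pytest.fixture
def occ_csv(tmp_path):
    """Write occurrence-table text to a temp file and return the path."""

    def _write(text: str):
        p = tmp_path / "occ.csv"
        p.write_text(text, encoding="utf-8")
        return p

    return _write


@pytest.fixture
def cherry_tree():
    return DatedTree.from_newick("(A:2,B:2);")


@pytest.fixture
def three_tip_tree():
    return DatedTree.from_newick("((A:1,B:1):1,C:2);")


def make_records(species_widths, source="museum", sex="unknown", lat=45.0, lon=10.0):
    """Records from {species: [widths]} at a shared location."""
    out = []
    for sp, widths in species_widths.items():
        for w in widths:
            out.append(OccurrenceRecord(sp, sex, float(w), lat, lon, source))
    return out
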