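import numpy as np
import pytest

from indelpanel import generate_panel, to_binary_matrix
from indelpanel.markers import MarkerDef, MarkerGenotypeTable
from indelpanel.refpanel import build_reference_genotype_table
from indelpanel.simulate import PanelSpec


@pytest.fixture(scope="session")
def reference_table():
    """Deterministic 204-accession table with the published per-locus
    genotype-class counts."""
    return build_reference_genotype_table()


@pytest.fixture(scope="session")
def default_panel():
    """One synthetic panel drawn under the default study conditions."""
    return generate_panel(PanelSpec(seed=11))


@pytest.fixture(scope="session")
def default_binary(default_panel):
    tab, _, _ = default_panel
    return to_binary_matrix(tab)


def make_table(calls, marker_ids=None, accession_ids=None):
    """Small genotype table from an int array of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, l = calls.shape
    marker_ids = marker_ids or [f"M{j+1}" for j in range(l)]
    accession_ids = accession_ids or [f"a{i+1}" for i in range(n)]
    defs = [
        MarkerDef(m, gene=m, allele_ids=("A", "B"), band_bp={"A": 100, "B": 150})
        for m in marker_ids
    ]
    return MarkerGenotypeTable(accession_ids, defs, calls)
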