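import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pocketvote import parse_pdb
from pocketvote.template_pipeline import TemplateEntry


def load_templates(paths):
    """Parse template PDB files into TemplateEntry objects."""
    entries = []
    for p in paths:
        structure, ligands = parse_pdb(p)
        entries.append(TemplateEntry(template_id=p.stem, structure=structure,
                                     ligands=ligands))
    return entries


@pytest.fixture(scope="session")
def figure1_bundle(tmp_path_factory):
    from pocketvote.fixtures import figure1
    return figure1(tmp_path_factory.mktemp("fig1"), seed=0)


@pytest.fixture(scope="session")
def planted_bundle(tmp_path_factory):
    from pocketvote.fixtures import make_planted_bundle
    return make_planted_bundle(tmp_path_factory.mktemp("planted"),
                               n_templates=5, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
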