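import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from srnaevo.pipeline import run_all
from srnaevo.synthdata import make_fixture_dataset
from srnaevo.treeio import parse_newick

# small rooted trees (<= 6 leaves) used by the enumeration-oracle tests
SMALL_TREE_NEWICKS = [
    "(A:0.5,B:0.8):0;",
    "((A:0.3,B:0.5):0.2,C:0.7):0;",
    "((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.6):0;",
    "(((A:0.2,B:0.4):0.3,C:0.1):0.5,(D:0.6,E:0.2):0.4):0;",
    "((A:0.1,B:0.2,C:0.3):0.4,(D:0.5,(E:0.1,F:0.6):0.2):0.3):0;",  # polytomy
    "((A:0.0,B:0.3):0.2,C:0.4):0;",  # zero-length branch
]


@pytest.fixture(params=SMALL_TREE_NEWICKS, ids=lambda s: f"{s.count(',')+1}leaf")
def small_tree(request):
    return parse_newick(request.param)


@pytest.fixture(scope="session")
def paper_fixture(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("paperlike")
    return make_fixture_dataset(preset="paper-like", seed=17, outdir=outdir)


@pytest.fixture(scope="session")
def paper_run(paper_fixture, tmp_path_factory):
    out = tmp_path_factory.mktemp("paperlike_out")
    fam, scen, manifest = run_all(paper_fixture.outdir, out)
    return {
        "fam": fam,
        "scen": scen,
        "manifest": manifest,
        "fixture": paper_fixture,
        "outdir": out,
    }
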