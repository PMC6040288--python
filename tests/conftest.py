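import pytest

import phytonet as pn


@pytest.fixture(scope="session")
def reference_table() -> pn.CompoundTable:
    """The packaged 32-compound ATR property table."""
    return pn.load_reference_compounds()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A full synthetic input bundle plus its ground truth and directory."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = pn.GeneratorConfig(seed=7)
    truth = pn.write_bundle(cfg, outdir)
    return cfg, truth, outdir


@pytest.fixture()
def tiny_net() -> pn.BipartiteNetwork:
    """Two compounds sharing one target plus one private target each."""
    edges = [("C1", "TA"), ("C2", "TA"), ("C1", "TB"), ("C2", "TC")]
    return pn.BipartiteNetwork({"C1", "C2"}, {"TA", "TB", "TC"}, edges)
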