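import pytest

from venomics import datasets, parse_newick


@pytest.fixture(scope="session")
def habu_table():
    return datasets.habu_abundance()


@pytest.fixture()
def five_tip_tree():
    # depths: A,B = 1.0; C,D = 1.0; E = 1.0 (ultrametric)
    return parse_newick("((A:0.3,B:0.3):0.7,((C:0.4,D:0.4):0.35,E:0.75):0.25);")


@pytest.fixture()
def six_tip_tree():
    return parse_newick(
        "(((t1:0.2,t2:0.2):0.5,(t3:0.4,t4:0.4):0.3):0.3,(t5:0.6,t6:0.6):0.4);"
    )


@pytest.fixture()
def star_tree():
    return parse_newick("(A:1,B:1,C:1,D:1,E:1);")
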