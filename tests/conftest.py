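import numpy as np
import pytest

import traitdiv as td


def star_tree(n: int, length: float = 1.0, genus: str = "x") -> td.Phylogeny:
    tips = ",".join(f"t{i}_{genus}:{length}" for i in range(n))
    return td.parse_newick(f"({tips});")


def random_yule_tree(seed: int, n_tips: int = 20, lam: float = 0.3) -> td.Phylogeny:
    return td.simulate_bd_tree(lam, 0.0, n_tips=n_tips, seed=seed)


def rescale_depth(tree: td.Phylogeny, depth: float) -> td.Phylogeny:
    """Return a copy with branch lengths scaled to the requested depth."""
    c = depth / tree.depth
    text = tree.to_newick()
    out = td.parse_newick(text, strict=False)
    for node in out._tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= c
    return td.parse_newick(out.to_newick())


@pytest.fixture(scope="session")
def balanced8():
    """Perfectly balanced 8-tip tree with internal ages 1.0, 2.5 and 6.0."""
    cherry = "({a}_g:1.0,{b}_g:1.0):1.5"
    left = "(" + cherry.format(a="A", b="B") + "," + cherry.format(a="C", b="D") + "):3.5"
    right = "(" + cherry.format(a="E", b="F") + "," + cherry.format(a="G", b="H") + "):3.5"
    return td.parse_newick(f"({left},{right});")


@pytest.fixture(scope="session")
def coupled_fixture():
    """Synthetic study with a strong trait-rate/speciation coupling."""
    return td.generate_study_fixture(seed=11, n_tips=250, n_shifts=4,
                                     coupling=2.0, n_genera=25)


@pytest.fixture(scope="session")
def null_fixture():
    """Synthetic study with no trait-rate/speciation coupling."""
    return td.generate_study_fixture(seed=23, n_tips=250, n_shifts=4,
                                     coupling=0.0, n_genera=25)
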