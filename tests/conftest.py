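import pytest

from cnvprior.ontology import AnnotationGraph, Taxonomy, propagate_annotations


@pytest.fixture
def diamond():
    """8-term DAG with a diamond (C below both A and B) and 8 annotated genes.

        R
       / \\
      A   B
     / \\ / \\
    D   C   F
        |
        E
    """
    edges = [
        ("A", "R"), ("B", "R"),
        ("C", "A"), ("C", "B"),
        ("D", "A"), ("F", "B"),
        ("E", "C"), ("G", "F"),
    ]
    tax = Taxonomy("RABCDEFG", [(c, p) for c, p in edges])
    raw_pairs = [
        ("E", "g1"), ("E", "g2"),        # deep diamond leaf
        ("C", "g3"),
        ("D", "g4"), ("D", "g5"), ("D", "g6"),
        ("F", "g7"),
        ("B", "g8"),
    ]
    raw = AnnotationGraph.from_pairs([(t, n) for t, n in raw_pairs])
    ag = propagate_annotations(tax, raw)
    parent_edges = set(edges)
    return tax, raw, ag, parent_edges, set(raw_pairs)


@pytest.fixture(scope="session")
def planted_bundle():
    """The canonical planted-signal cohort used by the end-to-end tests."""
    from cnvprior.simulate import make_bundle

    return make_bundle(seed=1, benign_ratio=1.0)


@pytest.fixture(scope="session")
def planted_resources(planted_bundle):
    return planted_bundle.resources()
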