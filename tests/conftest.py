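import numpy as np
import pytest

import paleoshift as ps


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_ranges(**kw):
    """Build DatedTaxon dict from name=(fad, lad) keywords."""
    return {k: ps.DatedTaxon(k, float(f), float(l)) for k, (f, l) in kw.items()}


def balanced_newick(n, prefix="t"):
    """Newick string of a fully balanced rooted tree on n tips."""
    def rec(k, pre):
        if k == 1:
            return pre
        h = k // 2
        return f"({rec(h, pre + 'a')},{rec(k - h, pre + 'b')})"
    return rec(n, prefix) + ";"


@pytest.fixture
def five_tip_ctree():
    """Calibrated 5-tip tree with mixed ranges and positive branch durations."""
    tree = ps.read_tree("((A,B),((C,D),E));")
    ranges = make_ranges(
        A=(300, 290), B=(295, 285), C=(280, 270), D=(285, 275), E=(290, 280)
    )
    return ps.calibrate(tree, ranges, min_branch=2.0)
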