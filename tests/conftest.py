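import numpy as np
import pytest

from morphclock.io_formats import (Calibration, CalibrationTable,
                                   CharacterMatrix)
from morphclock.treedata import Node, TimeTree


@pytest.fixture
def two_taxon_tree():
    root = Node(1.0)
    a = root.add_child(Node(0.0, "A"))
    b = root.add_child(Node(0.0, "B"))
    return TimeTree(root), a, b


@pytest.fixture
def four_taxon_tree():
    """((A,B):y=3, (C,D):z=5) with root at 10."""
    root = Node(10.0)
    y = root.add_child(Node(3.0))
    z = root.add_child(Node(5.0))
    y.add_child(Node(0.0, "A"))
    y.add_child(Node(0.0, "B"))
    z.add_child(Node(0.0, "C"))
    z.add_child(Node(0.0, "D"))
    return TimeTree(root)


@pytest.fixture
def six_taxon_data():
    """Four extant + two fossil taxa with a tiny binary matrix."""
    taxa = ["A", "B", "C", "D", "F1", "F2"]
    cells = [[0, 0], [0, 1], [1, 0], [1, 1], [0, 0], [1, 1]]
    matrix = CharacterMatrix(taxa, cells, [2, 2])
    calibrations = CalibrationTable({
        "A": Calibration(0, 0), "B": Calibration(0, 0),
        "C": Calibration(0, 0), "D": Calibration(0, 0),
        "F1": Calibration(20, 30), "F2": Calibration(45, 60),
    })
    return matrix, calibrations


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
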