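import numpy as np
import pytest

from imcsim.core_model import CellType, ForceParameters, IMCState


@pytest.fixture
def params():
    return ForceParameters()


@pytest.fixture
def border_pair():
    """Two border cells 0.8 diameters apart along x (3D)."""

    def _make(separation=0.8, dimension=3):
        p0 = np.zeros(dimension)
        p1 = np.zeros(dimension)
        p1[0] = separation
        return [
            IMCState(id=0, position=p0, cell_type=CellType.BORDER),
            IMCState(id=1, position=p1, cell_type=CellType.BORDER),
        ]

    return _make


def make_cell(cid, position, cell_type, group_id=0, fixed=False):
    return IMCState(
        id=cid,
        position=np.asarray(position, dtype=float),
        cell_type=cell_type,
        group_id=group_id,
        fixed=fixed,
    )
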