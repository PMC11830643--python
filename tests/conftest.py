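import numpy as np
import pytest
import trimesh

import valvemorph as vm
from valvemorph import phylocomp as pc


@pytest.fixture
def cube():
    """Closed unit cube centred on the origin, outward normals."""
    box = trimesh.creation.box()
    return vm.ValveMesh(np.asarray(box.vertices), np.asarray(box.faces))


@pytest.fixture(scope="session")
def hemisphere_factory():
    """Open hemi-ellipsoid surfaces (z >= 0) at a chosen resolution."""
    from valvemorph.synthdata import _hemi_faces, _hemi_grid

    def build(a=1.0, b=1.0, c=1.0, n_rings=32):
        n_seg = 2 * n_rings
        verts = _hemi_grid(a, b, c, n_rings, n_seg)
        faces = _hemi_faces(n_rings, n_seg)
        return vm.ValveMesh(verts, faces, role="interior_surface")

    return build


@pytest.fixture(scope="session")
def bd_tree64():
    """64-tip birth-death tree shared by the calibration tests."""
    return vm.simulate_tree(64, birth=0.3, death=0.1, seed=5)


@pytest.fixture(scope="session")
def bd_tree64_vcv(bd_tree64):
    C, labels = pc.phylo_vcv(bd_tree64)
    return C, labels


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic study cohort (4 families, 250 species)."""
    return vm.make_cohort(seed=11)
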