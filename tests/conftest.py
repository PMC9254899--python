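"""Shared fixtures: small toy cells/sets and a session-scoped benchmark run."""
import numpy as np
import pytest

from serialmerge.lattice import UnitCell
from serialmerge.reflections import ReflectionSet, asu_key_set, unpack_hkl


@pytest.fixture
def cubic_cell():
    return UnitCell(10, 10, 10, 90, 90, 90)


def make_set(dataset_id, hkl, intensities, cell=None, laue_group="-1",
             sigmas=None, merged=True):
    hkl = np.asarray(hkl)
    intensities = np.asarray(intensities, dtype=float)
    if sigmas is None:
        sigmas = np.full(len(intensities), 0.1)
    return ReflectionSet(dataset_id, hkl, intensities, sigmas, cell=cell,
                         laue_group=laue_group, merged=merged)


@pytest.fixture
def toy_triplet(cubic_cell):
    """Three merged sets sharing three indices with intensities
    (1,2,3), (1,2,4), (3,2,1)."""
    hkl = [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
    mk = lambda name, vals: make_set(name, hkl, vals, cell=cubic_cell)
    return mk("x", [1, 2, 3]), mk("y", [1, 2, 4]), mk("z", [3, 2, 1])


@pytest.fixture(scope="session")
def full_sphere_keys():
    """Sorted ASU keys of the cubic a=10 cell, Laue -1, d_min 5 (16 indices)."""
    cell = UnitCell(10, 10, 10, 90, 90, 90)
    return np.array(sorted(asu_key_set(cell, "-1", 5.0)))


def set_from_keys(name, keys, cell, laue_group="-1", intensity=1.0):
    keys = np.asarray(keys)
    return ReflectionSet(name, unpack_hkl(keys),
                         np.full(len(keys), float(intensity)),
                         np.full(len(keys), 0.1),
                         cell=cell, laue_group=laue_group, merged=True)


@pytest.fixture(scope="session")
def benchmark_run():
    """Full four-form benchmark (1000 wedges, canonical seed) plus the
    two-stage run; shared by the heavier end-to-end tests."""
    from serialmerge.pipeline import RunConfig, run_two_stage
    from serialmerge.synthetic import generate_paper_like

    exp = generate_paper_like()
    cfg = RunConfig()
    result = run_two_stage(cfg, cells=exp.cells(), sets=exp.sets(),
                           ids=exp.ids, truth=exp.truth)
    return exp, result
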