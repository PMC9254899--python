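"""HKL I/O, Laue symmetry / ASU mapping, completeness, merging, CC, SFDist."""
import itertools
import math

import numpy as np
import pytest

from serialmerge.errors import (
    EmptySetError,
    HKLFormatError,
    HKLParseError,
    InsufficientOverlapError,
    InvalidIndexError,
    SerialMergeError,
    UndefinedCCError,
)
from serialmerge.lattice import UnitCell
from serialmerge.reflections import (
    LaueGroup,
    Reflection,
    ReflectionSet,
    asu_key_set,
    completeness,
    map_to_asu,
    merge_sets,
    pearson_cc,
    read_hkl,
    sfdist,
    sfdist_matrix,
    unpack_hkl,
    write_hkl,
)
from conftest import make_set, set_from_keys

SUPPORTED_GROUPS = ["-1", "2/m", "mmm", "4/m", "4/mmm"]


# ---------------------------------------------------------------------------
# HKL4 I/O
# ---------------------------------------------------------------------------


def test_read_hkl_record_format(tmp_path):
    p = tmp_path / "a.hkl"
    p.write_text("   1   2   3  100.00    5.00\n   0   0   0    0.00    0.00\n")
    rs = read_hkl(p)
    assert rs.dataset_id == "a"
    assert rs.observations == [Reflection(1, 2, 3, 100.0, 5.0)]


def test_read_hkl_terminator_stops_parsing(tmp_path):
    p = tmp_path / "t.hkl"
    p.write_text(
        "   1   2   3  100.00    5.00\n"
        "   0   0   0    0.00    0.00\n"
        "   9   9   9    1.00    1.00\n"
    )
    assert len(read_hkl(p)) == 1


def test_write_read_roundtrip(tmp_path, cubic_cell):
    rs = make_set("r", [[1, 2, 3], [-4, 5, -6], [7, 0, 1]],
                  [1.25, -3.5, 12345.67], cell=cubic_cell,
                  sigmas=[0.25, 1.0, 99.99])
    p = tmp_path / "r.hkl"
    write_hkl(rs, p)
    assert p.read_text().count("\n") == 4  # 3 records + terminator
    back = read_hkl(p, cell=cubic_cell, laue_group="-1", merged=True)
    assert np.array_equal(back.hkl, rs.hkl)
    assert np.array_equal(back.intensity, rs.intensity)
    assert np.array_equal(back.sigma, rs.sigma)


def test_write_empty_set_is_terminator_only(tmp_path):
    rs = ReflectionSet("e", np.empty((0, 3)), [], [])
    p = tmp_path / "e.hkl"
    write_hkl(rs, p)
    assert p.read_text() == "   0   0   0    0.00    0.00\n"


def test_hkl_errors(tmp_path):
    p = tmp_path / "bad.hkl"
    p.write_text("   1   2   3   abc      5.00\n")
    with pytest.raises(HKLParseError, match="bad.hkl:1"):
        read_hkl(p)
    p.write_text("  1 2\n")
    with pytest.raises(HKLParseError):
        read_hkl(p)
    p.write_text("")
    with pytest.raises(EmptySetError):
        read_hkl(p)
    big = make_set("big", [[1, 1, 1]], [1.5e6])
    with pytest.raises(HKLFormatError):
        write_hkl(big, tmp_path / "o.hkl")


# ---------------------------------------------------------------------------
# Laue groups and ASU mapping
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("symbol,order", [("-1", 2), ("2/m", 4), ("mmm", 8),
                                          ("4/m", 8), ("4/mmm", 16)])
def test_group_orders(symbol, order):
    assert LaueGroup.from_symbol(symbol).order == order


def test_map_to_asu_examples():
    assert map_to_asu(-1, -2, -3, "-1") == (1, 2, 3)
    assert map_to_asu(1, 2, 3, "4/mmm") == (2, 1, 3)
    with pytest.raises(InvalidIndexError):
        map_to_asu(0, 0, 0, "-1")


@pytest.mark.parametrize("symbol", SUPPORTED_GROUPS)
def test_asu_mapping_partitions_index_space(symbol):
    """Exhaustively over |h|,|k|,|l| <= 4: the canonical index is idempotent,
    belongs to its own orbit, and the whole orbit shares one canonical."""
    group = LaueGroup.from_symbol(symbol)
    for hkl in itertools.product(range(-4, 5), repeat=3):
        if hkl == (0, 0, 0):
            continue
        canon = map_to_asu(*hkl, group)
        assert map_to_asu(*canon, group) == canon
        orbit = {tuple(int(x) for x in op @ np.array(hkl))
                 for op in group.operators}
        assert canon in orbit
        assert all(map_to_asu(*img, group) == canon for img in orbit)


def test_group_from_file(tmp_path):
    p = tmp_path / "ops.txt"
    p.write_text("-1 0 0\n0 1 0\n0 0 -1\n")  # 2-fold along b
    g = LaueGroup.from_file(p)
    assert g.order == LaueGroup.from_symbol("2/m").order


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------


def test_asu_denominator_cubic_friedel(cubic_cell):
    # h^2+k^2+l^2 <= 4 gives 32 lattice points, halved by Friedel
    assert len(asu_key_set(cubic_cell, "-1", 5.0)) == 16


@pytest.mark.parametrize("symbol", SUPPORTED_GROUPS)
def test_asu_denominator_matches_orbit_enumeration(symbol, cubic_cell):
    full = asu_key_set(cubic_cell, symbol, 5.0)
    # independent count: orbits of the 32-point sphere under the group
    group = LaueGroup.from_symbol(symbol)
    pts = [p for p in itertools.product(range(-2, 3), repeat=3)
           if p != (0, 0, 0) and sum(x * x for x in p) <= 4]
    orbits = set()
    for p in pts:
        orbit = frozenset(tuple(int(x) for x in op @ np.array(p))
                          for op in group.operators)
        orbits.add(orbit)
    assert len(full) == len(orbits)


def test_completeness_half_full_empty(cubic_cell, full_sphere_keys):
    half = set_from_keys("h", full_sphere_keys[:8], cubic_cell)
    full = set_from_keys("f", full_sphere_keys, cubic_cell)
    empty = ReflectionSet("e", np.empty((0, 3)), [], [], cell=cubic_cell,
                          laue_group="-1", merged=True)
    assert completeness(half, 5.0) == 0.5
    assert completeness(full, 5.0) == 1.0
    assert completeness(empty, 5.0) == 0.0
    with pytest.raises(SerialMergeError):
        completeness(full, -1.0)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def test_merge_single_set_identity(cubic_cell):
    s = make_set("s", [[1, 2, 3], [2, 0, 0]], [5.0, 6.0], cell=cubic_cell)
    m = merge_sets([s], scale_mode="none")
    assert m.merged and len(m) == 2
    assert sorted(m.intensity) == [5.0, 6.0]


def test_merge_inverse_variance_weighting(cubic_cell):
    a = make_set("a", [[1, 2, 3]], [10.0], cell=cubic_cell, sigmas=[1.0])
    b = make_set("b", [[1, 2, 3]], [20.0], cell=cubic_cell, sigmas=[2.0])
    m = merge_sets([a, b], scale_mode="none")
    assert m.intensity[0] == pytest.approx(12.0)
    assert m.sigma[0] == pytest.approx((1 + 0.25) ** -0.5)


def test_merge_disjoint_halves_full_completeness(cubic_cell, full_sphere_keys):
    a = set_from_keys("a", full_sphere_keys[:8], cubic_cell)
    b = set_from_keys("b", full_sphere_keys[8:], cubic_cell)
    m = merge_sets([a, b])
    assert completeness(m, 5.0) == 1.0
    # union of unique indices conserved
    assert set(m.asu_keys()) == set(full_sphere_keys)


def test_merge_identical_observations_unchanged(cubic_cell):
    sets = [make_set(f"s{i}", [[1, 2, 3]], [7.5], cell=cubic_cell,
                     sigmas=[0.5]) for i in range(4)]
    m = merge_sets(sets, scale_mode="none")
    assert m.intensity[0] == pytest.approx(7.5)


def test_merge_linear_scaling_recovers_scale(cubic_cell, full_sphere_keys):
    rng = np.random.default_rng(3)
    inten = rng.exponential(1.0, len(full_sphere_keys)) + 0.1
    a = ReflectionSet("a", unpack_hkl(full_sphere_keys), inten,
                      0.05 * inten, cell=cubic_cell, laue_group="-1", merged=True)
    b = ReflectionSet("b", unpack_hkl(full_sphere_keys), 3.0 * inten,
                      0.15 * inten, cell=cubic_cell, laue_group="-1", merged=True)
    m = merge_sets([a, b], scale_mode="linear")
    assert m.intensity == pytest.approx(inten, rel=1e-9)


def test_merge_rejects_mixed_or_empty(cubic_cell):
    a = make_set("a", [[1, 2, 3]], [1.0], cell=cubic_cell, laue_group="-1")
    b = make_set("b", [[1, 2, 3]], [1.0], cell=cubic_cell, laue_group="mmm")
    with pytest.raises(SerialMergeError):
        merge_sets([a, b])
    with pytest.raises(SerialMergeError):
        merge_sets([])


# ---------------------------------------------------------------------------
# CC and SFDist
# ---------------------------------------------------------------------------


def test_cc_identical_and_anticorrelated(toy_triplet):
    x, _, z = toy_triplet
    res = pearson_cc(x, x)
    assert res.cc == pytest.approx(1.0) and res.f_unmatched == 0.0
    assert pearson_cc(x, z).cc == pytest.approx(-1.0)


def test_cc_printed_toy_value(toy_triplet):
    x, y, _ = toy_triplet
    assert pearson_cc(x, y).cc == pytest.approx(3 / (math.sqrt(2) * math.sqrt(42 / 9)))


def test_cc_scale_and_offset_invariance(cubic_cell):
    rng = np.random.default_rng(5)
    hkl = [[h, k, l] for h in range(1, 4) for k in range(3) for l in range(3)]
    vals = rng.exponential(1.0, len(hkl))
    a = make_set("a", hkl, vals, cell=cubic_cell)
    b = make_set("b", hkl, 4.2 * vals + 3.0, cell=cubic_cell)
    assert pearson_cc(a, b).cc == pytest.approx(1.0)


def test_cc_preconditions(toy_triplet, cubic_cell):
    x, _, _ = toy_triplet
    tiny = make_set("t", [[1, 2, 3], [9, 9, 9]], [1.0, 2.0], cell=cubic_cell)
    with pytest.raises(InsufficientOverlapError):
        pearson_cc(x, tiny)
    flat = make_set("f", [[1, 2, 3], [2, 3, 4], [3, 4, 5]], [2.0, 2.0, 2.0],
                    cell=cubic_cell)
    with pytest.raises(UndefinedCCError):
        pearson_cc(x, flat)


def test_sfdist_closed_forms(toy_triplet):
    x, _, z = toy_triplet
    assert sfdist(x, x) == pytest.approx(0.0, abs=1e-7)
    # full overlap, cc = -1 -> sqrt(2*2) = 2
    assert sfdist(x, z) == pytest.approx(2.0)
    # cc = 0 at full overlap -> sqrt(2)
    a = make_set("a", [[1, 2, 3], [2, 3, 4], [3, 4, 5]], [1.0, 0.0, -1.0])
    b = make_set("b", [[1, 2, 3], [2, 3, 4], [3, 4, 5]], [1.0, -2.0, 1.0])
    assert sfdist(a, b) == pytest.approx(math.sqrt(2))


def test_sfdist_monotone_in_cc_and_unmatched(cubic_cell, full_sphere_keys):
    rng = np.random.default_rng(9)
    base = rng.exponential(1.0, 16)
    ref = set_from_keys("r", full_sphere_keys, cubic_cell)
    ref.intensity[:] = base
    prev = -1.0
    # decreasing cc -> increasing distance (mix in more anti-signal)
    for w in (0.0, 0.3, 0.7, 1.0):
        other = set_from_keys("o", full_sphere_keys, cubic_cell)
        other.intensity[:] = (1 - w) * base + w * base[::-1]
        d = sfdist(ref, other)
        assert d > prev - 1e-12
        prev = d
    # increasing unmatched fraction at matched cc -> increasing distance
    d_full = sfdist(ref, ref)
    partial = set_from_keys("p", full_sphere_keys[:8], cubic_cell)
    partial.intensity[:] = base[:8]
    d_partial = sfdist(ref, partial)
    assert d_partial > d_full
    # the penalty is exactly weight * f_unmatched here (cc = 1 on common)
    assert d_partial == pytest.approx(1.0 * 0.5, abs=1e-6)


def test_sfdist_penalty_gated_by_activation(cubic_cell, full_sphere_keys):
    base = np.linspace(1, 2, 16)
    ref = set_from_keys("r", full_sphere_keys, cubic_cell)
    ref.intensity[:] = base
    sub = set_from_keys("s", full_sphere_keys[:15], cubic_cell)
    sub.intensity[:] = base[:15]
    # common fraction 15/16 > 0.9: no penalty
    assert sfdist(ref, sub) == pytest.approx(0.0, abs=1e-7)
    # raising the activation threshold turns the penalty on
    assert sfdist(ref, sub, activation_threshold=0.99) == pytest.approx(
        1.0 / 16.0, abs=1e-6)


def test_sfdist_matrix_consistency_and_sentinel(toy_triplet, cubic_cell):
    x, y, z = toy_triplet
    D, failures = sfdist_matrix([x, y, z])
    assert not failures
    assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)
    for i, a in enumerate((x, y, z)):
        for j, b in enumerate((x, y, z)):
            if i != j:
                assert D[i, j] == pytest.approx(sfdist(a, b))
    # permutation equivariance
    D2, _ = sfdist_matrix([z, x, y])
    perm = [2, 0, 1]
    assert np.allclose(D2, D[np.ix_(perm, perm)])
    # non-overlapping pair becomes a sentinel, reported
    w = make_set("w", [[5, 5, 5], [6, 6, 6], [7, 7, 7]], [1.0, 2.0, 3.0],
                 cell=cubic_cell)
    D3, fails = sfdist_matrix([x, y, w], sentinel=10.0)
    assert D3[0, 2] == 10.0 and D3[1, 2] == 10.0
    assert len(fails) == 2
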