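"""Unit cells, the G6 metric embedding, Niggli reduction and lattice distances.

A unit cell (a, b, c, alpha, beta, gamma) is embedded in the six-dimensional
G6 space as the metric tensor with the last three components doubled,

    g = [a^2, b^2, c^2, 2bc*cos(alpha), 2ac*cos(beta), 2ab*cos(gamma)],

in which Niggli reduction canonicalizes the basis choice and a Niggli-cone
distance (``ncdist``) compares lattices while healing the discontinuities
that plague naive Euclidean comparison of cell parameters near reduction
boundaries.  The module also provides the classic PCA/Euclidean cell
distance used by BLEND as the less sensitive alternative.

Angles are degrees in all public I/O and radians only inside formulas.
G6 components and the distances derived from them are in Angstrom^2.
"""
from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    InsufficientDataError,
    InvalidCellError,
    InvalidMetricError,
    ReductionError,
)

__all__ = [
    "UnitCell",
    "G6Vector",
    "ReductionResult",
    "cell_to_g6",
    "g6_to_cell",
    "niggli_reduce",
    "ncdist",
    "ncdist_matrix",
    "blend_cell_distance_matrix",
    "cell_face_diagonals",
    "lcv",
    "g6_operators",
    "read_cells_csv",
    "write_cells_csv",
    "write_distance_tsv",
]


@dataclass(frozen=True)
class UnitCell:
    """Six unit-cell parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise InvalidCellError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0 < v < 180:
                raise InvalidCellError(f"cell angle {name} must lie in (0, 180)")
        if np.linalg.det(self.metric_tensor()) <= 0:
            raise InvalidCellError("cell metric is not positive definite")

    def metric_tensor(self) -> np.ndarray:
        """3x3 real-space metric tensor G with G_ij = a_i . a_j."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @property
    def volume(self) -> float:
        return float(math.sqrt(np.linalg.det(self.metric_tensor())))

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class G6Vector:
    """Metric-tensor embedding [a2, b2, c2, 2bc cos(alpha), 2ac cos(beta), 2ab cos(gamma)]."""

    g1: float
    g2: float
    g3: float
    g4: float
    g5: float
    g6: float

    def as_array(self) -> np.ndarray:
        return np.array([self.g1, self.g2, self.g3, self.g4, self.g5, self.g6])

    @staticmethod
    def from_array(g) -> "G6Vector":
        g = np.asarray(g, dtype=float)
        if g.shape != (6,):
            raise InvalidMetricError("G6 vector must have six components")
        return G6Vector(*(float(x) for x in g))

    def metric_tensor(self) -> np.ndarray:
        g1, g2, g3, g4, g5, g6 = self.as_array()
        return np.array(
            [
                [g1, g6 / 2.0, g5 / 2.0],
                [g6 / 2.0, g2, g4 / 2.0],
                [g5 / 2.0, g4 / 2.0, g3],
            ]
        )

    def validate(self) -> "G6Vector":
        if min(self.g1, self.g2, self.g3) <= 0:
            raise InvalidMetricError("g1, g2, g3 must be positive")
        if not (
            abs(self.g4) < 2 * math.sqrt(self.g2 * self.g3)
            and abs(self.g5) < 2 * math.sqrt(self.g1 * self.g3)
            and abs(self.g6) < 2 * math.sqrt(self.g1 * self.g2)
        ):
            raise InvalidMetricError("off-diagonal components violate positive-definiteness")
        if np.linalg.det(self.metric_tensor()) <= 0:
            raise InvalidMetricError("metric tensor is not positive definite")
        return self


@dataclass(frozen=True)
class ReductionResult:
    """Niggli reduction output: reduced G6 vector, integer basis change, status."""

    reduced: G6Vector
    transform: np.ndarray  # 3x3 integers, det +-1; rows give reduced basis in input basis
    converged: bool
    n_steps: int = 0


def cell_to_g6(cell: UnitCell) -> G6Vector:
    """Embed a unit cell in G6 (metric tensor with doubled cross terms)."""
    if not isinstance(cell, UnitCell):
        cell = UnitCell(*cell)
    a, b, c = cell.a, cell.b, cell.c
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    return G6Vector(a * a, b * b, c * c, 2 * b * c * ca, 2 * a * c * cb, 2 * a * b * cg)


def g6_to_cell(g: G6Vector) -> UnitCell:
    """Invert the G6 embedding back to (a, b, c, alpha, beta, gamma)."""
    if not isinstance(g, G6Vector):
        g = G6Vector.from_array(g)
    g.validate()
    a, b, c = math.sqrt(g.g1), math.sqrt(g.g2), math.sqrt(g.g3)
    alpha = math.degrees(math.acos(g.g4 / (2 * b * c)))
    beta = math.degrees(math.acos(g.g5 / (2 * a * c)))
    gamma = math.degrees(math.acos(g.g6 / (2 * a * b)))
    return UnitCell(a, b, c, alpha, beta, gamma)


# ---------------------------------------------------------------------------
# Niggli reduction (Krivy-Gruber stepwise algorithm with tolerances)
# ---------------------------------------------------------------------------

_SWAP_AB = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]])
_SWAP_BC = np.array([[1, 0, 0], [0, 0, 1], [0, 1, 0]])


def _g6_components(metric: np.ndarray):
    return (
        metric[0, 0],
        metric[1, 1],
        metric[2, 2],
        2 * metric[1, 2],
        2 * metric[0, 2],
        2 * metric[0, 1],
    )


def _sign3(x, eps):
    if x > eps:
        return 1
    if x < -eps:
        return -1
    return 0


def niggli_reduce(g: G6Vector, tol: float = 1e-5, max_steps: int = 1000) -> ReductionResult:
    """Reduce a G6 vector to its Niggli cell.

    Runs the stepwise basis-change algorithm with a relative tolerance on
    every boundary comparison, so near-degenerate cells (type I vs type II
    boundaries, near-cubic cells) are resolved consistently.  The returned
    transform ``M`` satisfies ``M G M^T = G_reduced`` on the metric tensors.
    """
    if not isinstance(g, G6Vector):
        g = G6Vector.from_array(g)
    g.validate()
    G0 = g.metric_tensor()
    M = np.eye(3, dtype=np.int64)
    eps = tol * max(g.g1, g.g2, g.g3)

    def comps():
        Gm = M @ G0 @ M.T
        return _g6_components(Gm)

    steps = 0
    while steps < max_steps:
        steps += 1
        A, B, C, xi, eta, zeta = comps()

        # step 1: order A <= B (tie broken on |xi| <= |eta|)
        if A > B + eps or (abs(A - B) <= eps and abs(xi) > abs(eta) + eps):
            M = _SWAP_AB @ M
            continue
        # step 2: order B <= C (tie broken on |eta| <= |zeta|)
        if B > C + eps or (abs(B - C) <= eps and abs(eta) > abs(zeta) + eps):
            M = _SWAP_BC @ M
            continue

        sx, sy, sz = _sign3(xi, eps), _sign3(eta, eps), _sign3(zeta, eps)
        if sx * sy * sz > 0:
            # step 3: make all angle terms positive (flip the axis common
            # to the two negative terms; product > 0 means zero or two are
            # negative)
            if sx < 0 and sy < 0:
                flip = np.diag([1, 1, -1])
            elif sx < 0 and sz < 0:
                flip = np.diag([1, -1, 1])
            elif sy < 0 and sz < 0:
                flip = np.diag([-1, 1, 1])
            else:
                flip = None
            if flip is not None:
                M = flip @ M
                continue
        else:
            # step 4: make all angle terms non-positive; a zero component,
            # tracked in z, absorbs the sign needed to keep the flip count even
            f = [1, 1, 1]
            z = -1
            for i, s in enumerate((sx, sy, sz)):
                if s > 0:
                    f[i] = -1
                elif s == 0:
                    z = i
            if f[0] * f[1] * f[2] < 0:
                if z >= 0:
                    f[z] = -f[z]
                else:  # numerically inconsistent signs; flip the smallest term
                    z = int(np.argmin([abs(xi), abs(eta), abs(zeta)]))
                    f[z] = -f[z]
            if f != [1, 1, 1]:
                M = np.diag(f) @ M
                continue

        A, B, C, xi, eta, zeta = comps()
        # step 5: |xi| <= B with boundary tie-breaks
        if abs(xi) > B + eps or (abs(xi - B) <= eps and 2 * eta < zeta - eps) or (
            abs(xi + B) <= eps and zeta < -eps
        ):
            s = 1 if xi > 0 else -1
            step = np.array([[1, 0, 0], [0, 1, 0], [0, -s, 1]])  # c' = c - s*b
            M = step @ M
            continue
        # step 6: |eta| <= A
        if abs(eta) > A + eps or (abs(eta - A) <= eps and 2 * xi < zeta - eps) or (
            abs(eta + A) <= eps and zeta < -eps
        ):
            s = 1 if eta > 0 else -1
            step = np.array([[1, 0, 0], [0, 1, 0], [-s, 0, 1]])  # c' = c - s*a
            M = step @ M
            continue
        # step 7: |zeta| <= A
        if abs(zeta) > A + eps or (abs(zeta - A) <= eps and 2 * xi < eta - eps) or (
            abs(zeta + A) <= eps and eta < -eps
        ):
            s = 1 if zeta > 0 else -1
            step = np.array([[1, 0, 0], [-s, 1, 0], [0, 0, 1]])  # b' = b - s*a
            M = step @ M
            continue
        # step 8: body-diagonal condition
        t = xi + eta + zeta + A + B
        if t < -eps or (abs(t) <= eps and 2 * (A + eta) + zeta > eps):
            step = np.array([[1, 0, 0], [0, 1, 0], [1, 1, 1]])  # c' = a + b + c
            M = step @ M
            continue

        reduced = G6Vector(*(float(x) for x in comps()))
        return ReductionResult(reduced=reduced, transform=M, converged=True, n_steps=steps)

    partial = ReductionResult(
        reduced=G6Vector(*(float(x) for x in comps())),
        transform=M,
        converged=False,
        n_steps=steps,
    )
    raise ReductionError(
        f"Niggli reduction did not converge within {max_steps} steps", partial=partial
    )


# ---------------------------------------------------------------------------
# NCDist: Niggli-cone distance in G6
# ---------------------------------------------------------------------------


def _build_g6_operators() -> np.ndarray:
    """The 24 G6 images of the proper axis permutation/sign-flip group.

    Basis change a'_i = s_i * a_{perm(i)} with an even number of sign flips
    acts linearly on G6; improper versions coincide with proper ones in G6
    because -I acts trivially on the metric.
    """
    ops = []
    seen = set()
    basis_mats = []
    for k in range(6):
        e = np.zeros(6)
        e[k] = 1.0
        basis_mats.append(G6Vector.from_array(e).metric_tensor())
    for perm in itertools.permutations(range(3)):
        for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
            P = np.zeros((3, 3))
            for i in range(3):
                P[i, perm[i]] = signs[i]
            cols = []
            for Gk in basis_mats:
                Gp = P @ Gk @ P.T
                cols.append(_g6_components(Gp))
            M6 = np.array(cols).T
            key = tuple(np.round(M6, 9).ravel())
            if key not in seen:
                seen.add(key)
                ops.append(M6)
    return np.array(ops)


_G6_OPERATORS = _build_g6_operators()


def g6_operators() -> np.ndarray:
    """The default NCDist transform set (24 G6 permutation/sign operators)."""
    return _G6_OPERATORS.copy()


def _reduced_array(g, tol=1e-5) -> np.ndarray:
    if isinstance(g, UnitCell):
        g = cell_to_g6(g)
    return niggli_reduce(g, tol=tol).reduced.as_array()


def ncdist(g_a, g_b, transforms: np.ndarray | None = None, tol: float = 1e-5) -> float:
    """Niggli-cone distance between two lattices, in Angstrom^2.

    Both arguments (cells or G6 vectors) are Niggli-reduced, then the
    minimum Euclidean G6 distance over the configured transform set applied
    to either reduced vector is returned.  The identity is always a member,
    so the result never exceeds the plain Euclidean distance between the two
    reduced vectors.  The default transform set is the orthogonal group of
    24 axis permutation/sign-flip operators; the result is an upper bound on
    the exact Niggli-cone geodesic.
    """
    ra = _reduced_array(g_a, tol)
    rb = _reduced_array(g_b, tol)
    T = _G6_OPERATORS if transforms is None else np.asarray(transforms)
    images = T @ rb  # (n_ops, 6)
    d = np.linalg.norm(images - ra, axis=1)
    return float(d.min())


def ncdist_matrix(cells, ids=None, transforms: np.ndarray | None = None, tol: float = 1e-5) -> np.ndarray:
    """Pairwise NCDist matrix over a list of cells (symmetric, zero diagonal)."""
    cells = list(cells)
    if len(cells) < 2:
        raise InsufficientDataError("need at least 2 cells for a distance matrix")
    if ids is None:
        ids = [str(i) for i in range(len(cells))]
    reduced = []
    for i, c in enumerate(cells):
        try:
            reduced.append(_reduced_array(c, tol))
        except ReductionError as exc:
            raise ReductionError(f"reduction failed for dataset {ids[i]}: {exc}",
                                 partial=exc.partial) from exc
    R = np.array(reduced)
    T = _G6_OPERATORS if transforms is None else np.asarray(transforms)
    n = len(R)
    best = np.full((n, n), np.inf)
    for M6 in T:
        np.minimum(best, cdist(R, R @ M6.T), out=best)
    # the operator set is a group, so min over one side is already symmetric;
    # enforce exact symmetry and a clean diagonal against rounding
    best = np.minimum(best, best.T)
    np.fill_diagonal(best, 0.0)
    return best


# ---------------------------------------------------------------------------
# Original BLEND distance: PCA on raw cell parameters
# ---------------------------------------------------------------------------


def blend_cell_distance_matrix(cells, variance_cutoff: float = 0.01) -> np.ndarray:
    """Euclidean distance in the significant principal components of
    (a, b, c, alpha, beta, gamma).

    Components whose explained-variance fraction is at least
    ``variance_cutoff`` are retained; with zero total variance the matrix is
    all zeros.
    """
    cells = list(cells)
    if len(cells) < 2:
        raise InsufficientDataError("need at least 2 cells for a distance matrix")
    X = np.array([c.parameters() if isinstance(c, UnitCell) else tuple(c) for c in cells])
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    if total <= 0:
        return np.zeros((len(cells), len(cells)))
    keep = (s**2) / total >= variance_cutoff
    scores = U[:, keep] * s[keep]
    D = cdist(scores, scores)
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# Linear cell variation (cluster isomorphism measure)
# ---------------------------------------------------------------------------


def cell_face_diagonals(cell: UnitCell) -> np.ndarray:
    """Longer diagonal of each of the three independent cell faces.

    Faces pair (b, c, alpha), (a, c, beta), (a, b, gamma); the longer
    parallelogram diagonal is sqrt(x^2 + y^2 + 2xy|cos(theta)|).
    """
    pairs = (
        (cell.b, cell.c, cell.alpha),
        (cell.a, cell.c, cell.beta),
        (cell.a, cell.b, cell.gamma),
    )
    return np.array(
        [math.sqrt(x * x + y * y + 2 * x * y * abs(math.cos(math.radians(t))))
         for x, y, t in pairs]
    )


def lcv(cells) -> tuple[float, float]:
    """(LCV %, aLCV Angstrom): maximum relative and absolute spread of the
    face diagonals over a group of cells.

    The maximum over member pairs of |d_i - d_j| on each face is attained by
    the extreme diagonals, so only per-face minima/maxima are needed.
    """
    diags = np.array([cell_face_diagonals(c) for c in cells])
    if len(diags) < 2:
        return 0.0, 0.0
    dmax = diags.max(axis=0)
    dmin = diags.min(axis=0)
    pct = 100.0 * (dmax - dmin) / dmin
    k = int(np.argmax(pct))
    return float(pct[k]), float(dmax[k] - dmin[k])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

CELLS_CSV_HEADER = ["dataset_id", "a", "b", "c", "alpha", "beta", "gamma", "hkl_path"]


def read_cells_csv(path):
    """Read the cells table; returns (ids, {id: UnitCell}, {id: hkl_path})."""
    ids, cells, paths = [], {}, {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CELLS_CSV_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise InvalidCellError(f"cells CSV missing columns: {sorted(missing)}")
        for row in reader:
            ds = row["dataset_id"]
            ids.append(ds)
            cells[ds] = UnitCell(
                float(row["a"]), float(row["b"]), float(row["c"]),
                float(row["alpha"]), float(row["beta"]), float(row["gamma"]),
            )
            paths[ds] = row["hkl_path"]
    return ids, cells, paths


def write_cells_csv(path, ids, cells, hkl_paths):
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CELLS_CSV_HEADER)
        for ds in ids:
            c = cells[ds]
            writer.writerow(
                [ds, f"{c.a:.6f}", f"{c.b:.6f}", f"{c.c:.6f}",
                 f"{c.alpha:.6f}", f"{c.beta:.6f}", f"{c.gamma:.6f}", hkl_paths[ds]]
            )


def write_distance_tsv(path, matrix, ids):
    """Write a labelled symmetric distance matrix as TSV."""
    matrix = np.asarray(matrix)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([""] + list(ids)) + "\n")
        for i, ds in enumerate(ids):
            fh.write("\t".join([ds] + [f"{x:.6g}" for x in matrix[i]]) + "\n")
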