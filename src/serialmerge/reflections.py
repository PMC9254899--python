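"""Reflection sets, SHELX HKL4 I/O, Laue symmetry, completeness, merging,
Pearson CC and the SFDist reflection-correlation distance.

A "reflection set" is one dataset's (or one merged cluster's) indexed
intensity observations.  Laue-group operators define which (h, k, l)
indices are symmetry-equivalent; every comparison between datasets happens
after mapping indices to a canonical asymmetric-unit (ASU) representative,
chosen as the lexicographically greatest image under the group.

The similarity between two merged sets is the Pearson correlation
coefficient of their intensities over common unique indices — the cosine of
the angle between the two mean-centred, norm-scaled intensity vectors,
which makes the comparison invariant to the unknown per-dataset scale.  It
is converted to the distance

    SFDist = sqrt(2 (1 - CC)) + w * f_unmatched        (penalty gated)

where the chord term is the Euclidean distance between the two unit
vectors whose angle-cosine is CC, and the penalty term (weight ``w`` on the
unmatched fraction of the index union) activates only when the common
fraction falls below a threshold (default 90%).
"""
from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    EmptySetError,
    HKLFormatError,
    HKLParseError,
    InsufficientDataError,
    InsufficientOverlapError,
    InvalidIndexError,
    MissingLabelError,
    SerialMergeError,
    UndefinedCCError,
)
from .lattice import UnitCell, lcv

__all__ = [
    "Reflection",
    "ReflectionSet",
    "LaueGroup",
    "CCResult",
    "read_hkl",
    "write_hkl",
    "map_to_asu",
    "map_indices_to_asu",
    "pack_hkl",
    "unpack_hkl",
    "asu_key_set",
    "completeness",
    "merge_sets",
    "pearson_cc",
    "sfdist",
    "sfdist_matrix",
]

# packed-integer encoding of (h, k, l); indices must satisfy |index| < _B
_B = 512
_S = 2 * _B


def pack_hkl(hkl: np.ndarray) -> np.ndarray:
    """Pack an (n, 3) integer index array into sortable int64 keys."""
    hkl = np.asarray(hkl, dtype=np.int64)
    if np.any(np.abs(hkl) >= _B):
        raise InvalidIndexError(f"Miller indices must satisfy |index| < {_B}")
    return ((hkl[..., 0] + _B) * _S + (hkl[..., 1] + _B)) * _S + hkl[..., 2] + _B


def unpack_hkl(keys: np.ndarray) -> np.ndarray:
    keys = np.asarray(keys, dtype=np.int64)
    l = keys % _S - _B
    rest = keys // _S
    k = rest % _S - _B
    h = rest // _S - _B
    return np.stack([h, k, l], axis=-1)


# ---------------------------------------------------------------------------
# Laue groups
# ---------------------------------------------------------------------------


def _closure(mats):
    ops = {m.tobytes(): m for m in mats}
    while True:
        new = {}
        for a, b in itertools.product(ops.values(), repeat=2):
            m = a @ b
            key = m.tobytes()
            if key not in ops and key not in new:
                new[key] = m
        if not new:
            return list(ops.values())
        ops.update(new)


_IDENT = np.eye(3, dtype=np.int64)
_INV = -_IDENT
_TWO_X = np.diag([1, -1, -1]).astype(np.int64)
_TWO_Y = np.diag([-1, 1, -1]).astype(np.int64)
_FOUR_Z = np.array([[0, 1, 0], [-1, 0, 0], [0, 0, 1]], dtype=np.int64)

_LAUE_GENERATORS = {
    "-1": [],
    "2/m": [_TWO_Y],
    "mmm": [_TWO_X, _TWO_Y],
    "4/m": [_FOUR_Z],
    "4/mmm": [_FOUR_Z, _TWO_X],
}


@dataclass(frozen=True)
class LaueGroup:
    """Point-group operators (including Friedel inversion) acting on hkl."""

    symbol: str
    operators: tuple  # tuple of 3x3 int64 arrays

    def __post_init__(self):
        keys = {op.tobytes() for op in self.operators}
        if _INV.tobytes() not in keys:
            raise SerialMergeError(f"Laue group {self.symbol} lacks -I")
        for a, b in itertools.product(self.operators, repeat=2):
            if (a @ b).tobytes() not in keys:
                raise SerialMergeError(f"Laue group {self.symbol} operators not closed")

    @property
    def order(self) -> int:
        return len(self.operators)

    def op_array(self) -> np.ndarray:
        return np.stack(self.operators)

    @classmethod
    @functools.lru_cache(maxsize=None)
    def from_symbol(cls, symbol: str) -> "LaueGroup":
        if symbol not in _LAUE_GENERATORS:
            raise SerialMergeError(
                f"unsupported Laue group {symbol!r}; built in: {sorted(_LAUE_GENERATORS)}"
            )
        mats = _closure([_IDENT, _INV] + _LAUE_GENERATORS[symbol])
        mats.sort(key=lambda m: tuple(m.ravel()))
        return cls(symbol, tuple(mats))

    @classmethod
    def from_file(cls, path, symbol: str | None = None) -> "LaueGroup":
        """Load operators from a text file: one 3x3 integer matrix per
        whitespace-separated block of nine numbers."""
        nums = Path(path).read_text().split()
        if len(nums) % 9 != 0:
            raise SerialMergeError("operator file must contain 3x3 integer blocks")
        mats = [
            np.array([int(x) for x in nums[i : i + 9]], dtype=np.int64).reshape(3, 3)
            for i in range(0, len(nums), 9)
        ]
        mats = _closure(mats + [_IDENT, _INV])
        mats.sort(key=lambda m: tuple(m.ravel()))
        return cls(symbol or Path(path).stem, tuple(mats))


def _as_group(group) -> LaueGroup:
    return group if isinstance(group, LaueGroup) else LaueGroup.from_symbol(group)


def map_to_asu(h: int, k: int, l: int, group) -> tuple[int, int, int]:
    """Canonical (lexicographically greatest) symmetry image of (h, k, l)."""
    if (h, k, l) == (0, 0, 0):
        raise InvalidIndexError("(0,0,0) has no ASU representative")
    out = map_indices_to_asu(np.array([[h, k, l]]), group)[0]
    return (int(out[0]), int(out[1]), int(out[2]))


def map_indices_to_asu(hkl: np.ndarray, group) -> np.ndarray:
    """Vectorized ASU mapping of an (n, 3) index array."""
    return unpack_hkl(asu_keys_of(hkl, group))


def asu_keys_of(hkl: np.ndarray, group) -> np.ndarray:
    """Packed canonical key per index; packing is lexicographic on (h,k,l),
    so the running maximum over operator images is the canonical choice."""
    group = _as_group(group)
    hkl = np.asarray(hkl, dtype=np.int64)
    best = None
    for op in group.operators:
        keys = pack_hkl(hkl @ op.T)
        best = keys if best is None else np.maximum(best, keys)
    return best


# ---------------------------------------------------------------------------
# Reflection data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reflection:
    h: int
    k: int
    l: int
    intensity: float
    sigma: float

    def __post_init__(self):
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise InvalidIndexError("reflection index (0,0,0) is not allowed")
        if not self.sigma > 0:
            raise SerialMergeError("sigma must be positive")


@dataclass
class ReflectionSet:
    """Indexed intensity observations with their cell and symmetry context.

    Observations are stored as parallel arrays (``hkl`` is (n, 3) int).  A
    merged set has every ASU-mapped index at most once.
    """

    dataset_id: str
    hkl: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    cell: UnitCell | None = None
    laue_group: str | None = None
    merged: bool = False

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, dtype=float).reshape(-1)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(-1)
        if not (len(self.hkl) == len(self.intensity) == len(self.sigma)):
            raise SerialMergeError("hkl/intensity/sigma lengths differ")
        if len(self.hkl) and np.any(~np.any(self.hkl != 0, axis=1)):
            raise InvalidIndexError("reflection index (0,0,0) is not allowed")
        if np.any(self.sigma <= 0):
            raise SerialMergeError("all sigmas must be positive")
        if self.merged and self.laue_group is not None:
            keys = self.asu_keys()
            if len(np.unique(keys)) != len(keys):
                raise SerialMergeError(
                    f"merged set {self.dataset_id} has duplicate ASU indices"
                )

    @classmethod
    def from_reflections(cls, dataset_id, reflections, **kw) -> "ReflectionSet":
        refs = list(reflections)
        hkl = np.array([(r.h, r.k, r.l) for r in refs], dtype=np.int64).reshape(-1, 3)
        inten = np.array([r.intensity for r in refs])
        sig = np.array([r.sigma for r in refs])
        return cls(dataset_id, hkl, inten, sig, **kw)

    @property
    def observations(self) -> list[Reflection]:
        return [
            Reflection(int(h), int(k), int(l), float(i), float(s))
            for (h, k, l), i, s in zip(self.hkl, self.intensity, self.sigma)
        ]

    def __len__(self):
        return len(self.hkl)

    def asu_keys(self) -> np.ndarray:
        """Packed canonical index per observation (requires laue_group)."""
        if self.laue_group is None:
            raise SerialMergeError(f"set {self.dataset_id} has no Laue group")
        if len(self.hkl) == 0:
            return np.empty(0, dtype=np.int64)
        return asu_keys_of(self.hkl, self.laue_group)

    def sorted_asu(self):
        """(sorted unique asu keys, intensities, sigmas); merged sets only."""
        if not self.merged:
            raise SerialMergeError("sorted_asu requires a merged set")
        keys = self.asu_keys()
        order = np.argsort(keys)
        return keys[order], self.intensity[order], self.sigma[order]

    def d_spacings(self) -> np.ndarray:
        if self.cell is None:
            raise SerialMergeError(f"set {self.dataset_id} has no cell")
        Gstar = np.linalg.inv(self.cell.metric_tensor())
        inv_d2 = np.einsum("ni,ij,nj->n", self.hkl.astype(float), Gstar,
                           self.hkl.astype(float))
        return 1.0 / np.sqrt(inv_d2)


# ---------------------------------------------------------------------------
# SHELX HKL4 I/O (fixed width 3I4,2F8.2)
# ---------------------------------------------------------------------------


def read_hkl(path, cell: UnitCell | None = None, laue_group: str | None = None,
             dataset_id: str | None = None, merged: bool = False) -> ReflectionSet:
    """Read a SHELX HKL4 file (3I4,2F8.2); the 0 0 0 record terminates."""
    path = Path(path)
    hkl, inten, sig = [], [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if len(line.rstrip("\n")) < 28:
                raise HKLParseError(f"{path.name}:{lineno}: record shorter than 28 columns")
            try:
                h = int(line[0:4])
                k = int(line[4:8])
                l = int(line[8:12])
                i = float(line[12:20])
                s = float(line[20:28])
            except ValueError as exc:
                raise HKLParseError(f"{path.name}:{lineno}: {exc}") from exc
            if (h, k, l) == (0, 0, 0):
                break
            hkl.append((h, k, l))
            inten.append(i)
            sig.append(s)
    if not hkl:
        raise EmptySetError(f"{path} contains no reflection records")
    return ReflectionSet(
        dataset_id or path.stem,
        np.array(hkl, dtype=np.int64),
        np.array(inten),
        np.array(sig),
        cell=cell,
        laue_group=laue_group,
        merged=merged,
    )


def write_hkl(rset: ReflectionSet, path) -> None:
    """Write SHELX HKL4 fixed-width records plus the 0 0 0 terminator.

    Sigmas are floored at 0.01 (the smallest value the F8.2 field can
    represent as positive).
    """
    lines = []
    for (h, k, l), i, s in zip(rset.hkl, rset.intensity, rset.sigma):
        if abs(i) >= 1e6 or abs(s) >= 1e6:
            raise HKLFormatError(
                f"value out of F8.2 column range for index ({h} {k} {l})"
            )
        if not (-1000 < h < 10000 and -1000 < k < 10000 and -1000 < l < 10000):
            raise HKLFormatError(f"index out of I4 column range: ({h} {k} {l})")
        lines.append(f"{h:4d}{k:4d}{l:4d}{i:8.2f}{max(s, 0.01):8.2f}\n")
    lines.append(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")
    Path(path).write_text("".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=4096)
def _asu_key_set_cached(cell_key, symbol, d_min) -> frozenset:
    a, b, c, al, be, ga = cell_key
    cell = UnitCell(a, b, c, al, be, ga)
    group = LaueGroup.from_symbol(symbol)
    Gstar = np.linalg.inv(cell.metric_tensor())
    hmax = int(cell.a / d_min) + 1
    kmax = int(cell.b / d_min) + 1
    lmax = int(cell.c / d_min) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    hf = hkl.astype(float)
    inv_d2 = np.einsum("ni,ij,nj->n", hf, Gstar, hf)
    hkl = hkl[inv_d2 <= 1.0 / d_min**2 * (1 + 1e-12)]
    return frozenset(np.unique(asu_keys_of(hkl, group)).tolist())


def asu_key_set(cell: UnitCell, group, d_min: float,
                cell_decimals: int = 4) -> frozenset:
    """All canonical ASU index keys with d >= d_min for a cell and Laue group.

    The cell is rounded to ``cell_decimals`` decimals for caching; the count
    of reflections inside the resolution sphere is insensitive to changes
    far below the experimental cell spread.
    """
    group = _as_group(group)
    if d_min <= 0:
        raise SerialMergeError("d_min must be positive")
    key = tuple(round(x, cell_decimals) for x in cell.parameters())
    return _asu_key_set_cached(key, group.symbol, round(float(d_min), 6))


def completeness(rset: ReflectionSet, d_min: float) -> float:
    """Fraction of unique ASU indices with d >= d_min present in the set."""
    if rset.cell is None or rset.laue_group is None:
        raise SerialMergeError(f"set {rset.dataset_id} needs cell and Laue group")
    full = asu_key_set(rset.cell, rset.laue_group, d_min)
    if len(rset) == 0:
        return 0.0
    present = set(np.unique(rset.asu_keys()).tolist()) & full
    return len(present) / len(full)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def _merge_within(keys, inten, sigma):
    """Inverse-variance merge of duplicate keys; returns sorted unique arrays."""
    order = np.argsort(keys, kind="stable")
    keys, inten, sigma = keys[order], inten[order], sigma[order]
    uniq, start = np.unique(keys, return_index=True)
    w = 1.0 / sigma**2
    wsum = np.add.reduceat(w, start)
    wisum = np.add.reduceat(w * inten, start)
    return uniq, wisum / wsum, np.sqrt(1.0 / wsum)


def merge_sets(sets, scale_mode: str = "none", max_lcv_percent: float = 2.0,
               dataset_id: str | None = None) -> ReflectionSet:
    """Merge reflection sets into one by inverse-variance weighted averaging.

    Observations are pooled after ASU mapping.  With ``scale_mode='linear'``
    each subsequent set is put on the scale of the running reference by a
    least-squares multiplier fitted on common indices before pooling; with
    ``'none'`` intensities are pooled as measured.  The output cell is the
    unweighted mean of the member cells.
    """
    sets = list(sets)
    if not sets:
        raise InsufficientDataError("merge_sets needs at least one set")
    symbols = {s.laue_group for s in sets}
    if len(symbols) != 1 or None in symbols:
        raise SerialMergeError(f"mixed or missing Laue groups: {symbols}")
    if scale_mode not in ("none", "linear"):
        raise SerialMergeError(f"unknown scale_mode {scale_mode!r}")
    cells = [s.cell for s in sets if s.cell is not None]
    if len(cells) == len(sets) and len(cells) > 1:
        pct, _ = lcv(cells)
        if pct > max_lcv_percent:
            raise SerialMergeError(
                f"member cells vary by LCV {pct:.2f}% > {max_lcv_percent}%"
            )

    acc_keys = acc_i = acc_s = None
    for s in sets:
        keys, inten, sigma = _merge_within(s.asu_keys(), s.intensity.copy(),
                                           s.sigma.copy())
        if acc_keys is None:
            acc_keys, acc_i, acc_s = keys, inten, sigma
            continue
        if scale_mode == "linear":
            common, ia, ib = np.intersect1d(acc_keys, keys, assume_unique=True,
                                            return_indices=True)
            if len(common) >= 2:
                denom = float(np.dot(inten[ib], inten[ib]))
                if denom > 0:
                    scale = float(np.dot(acc_i[ia], inten[ib])) / denom
                    if scale > 0:
                        inten = inten * scale
                        sigma = sigma * scale
        allk = np.concatenate([acc_keys, keys])
        alli = np.concatenate([acc_i, inten])
        alls = np.concatenate([acc_s, sigma])
        acc_keys, acc_i, acc_s = _merge_within(allk, alli, alls)

    if cells:
        params = np.array([c.parameters() for c in cells]).mean(axis=0)
        mean_cell = UnitCell(*params)
    else:
        mean_cell = None
    return ReflectionSet(
        dataset_id or "+".join(s.dataset_id for s in sets),
        unpack_hkl(acc_keys),
        acc_i,
        acc_s,
        cell=mean_cell,
        laue_group=sets[0].laue_group,
        merged=True,
    )


# ---------------------------------------------------------------------------
# Pearson CC and SFDist
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CCResult:
    cc: float
    n_common: int
    f_unmatched: float


def pearson_cc(a: ReflectionSet, b: ReflectionSet, min_common: int = 3,
               quantity: str = "intensity") -> CCResult:
    """Pearson CC of two merged sets over common unique indices.

    ``quantity='amplitude'`` compares sqrt(max(I, 0)) instead of I.
    """
    ka, ia, _ = a.sorted_asu()
    kb, ib, _ = b.sorted_asu()
    common, idx_a, idx_b = np.intersect1d(ka, kb, assume_unique=True,
                                          return_indices=True)
    n_common = len(common)
    n_union = len(ka) + len(kb) - n_common
    if n_common < min_common:
        raise InsufficientOverlapError(
            f"{a.dataset_id} vs {b.dataset_id}: only {n_common} common indices"
        )
    va, vb = ia[idx_a], ib[idx_b]
    if quantity == "amplitude":
        va, vb = np.sqrt(np.maximum(va, 0.0)), np.sqrt(np.maximum(vb, 0.0))
    elif quantity != "intensity":
        raise SerialMergeError(f"unknown comparison quantity {quantity!r}")
    va = va - va.mean()
    vb = vb - vb.mean()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise UndefinedCCError(
            f"{a.dataset_id} vs {b.dataset_id}: zero variance on common indices"
        )
    cc = float(np.clip(np.dot(va / na, vb / nb), -1.0, 1.0))
    return CCResult(cc=cc, n_common=n_common, f_unmatched=1.0 - n_common / n_union)


def _base_distance(cc: float, form: str) -> float:
    if form == "chord":
        return math.sqrt(max(2.0 * (1.0 - cc), 0.0))
    if form == "sine":
        return math.sqrt(max(1.0 - cc * cc, 0.0))
    raise SerialMergeError(f"unknown sfdist base form {form!r}")


def sfdist(a: ReflectionSet, b: ReflectionSet, penalty_weight: float = 1.0,
           activation_threshold: float = 0.90, base: str = "chord",
           min_common: int = 3, quantity: str = "intensity") -> float:
    """Correlation-derived distance between two merged reflection sets.

    The base term is the chord length between the unit vectors whose
    angle-cosine is CC (``sqrt(2(1-CC))``; ``base='sine'`` selects
    ``sqrt(1-CC^2)``).  When the common fraction of the index union is below
    ``activation_threshold`` a penalty ``penalty_weight * f_unmatched`` is
    added.
    """
    res = pearson_cc(a, b, min_common=min_common, quantity=quantity)
    d = _base_distance(res.cc, base)
    if (1.0 - res.f_unmatched) < activation_threshold:
        d += penalty_weight * res.f_unmatched
    return d


def sfdist_matrix(sets, penalty_weight: float = 1.0,
                  activation_threshold: float = 0.90, base: str = "chord",
                  min_common: int = 3, quantity: str = "intensity",
                  sentinel: float = 10.0):
    """Pairwise SFDist matrix; returns (matrix, failures).

    Pairs that fail the overlap or variance preconditions receive the
    ``sentinel`` distance and are reported in ``failures`` as
    (id_i, id_j, reason) for the run log.
    """
    sets = list(sets)
    if len(sets) < 2:
        raise InsufficientDataError("need at least 2 merged sets")
    cached = [s.sorted_asu() for s in sets]
    n = len(sets)
    D = np.zeros((n, n))
    failures = []
    for i in range(n):
        ka, ia, _ = cached[i]
        for j in range(i + 1, n):
            kb, ib, _ = cached[j]
            common, idx_a, idx_b = np.intersect1d(ka, kb, assume_unique=True,
                                                  return_indices=True)
            n_common = len(common)
            n_union = len(ka) + len(kb) - n_common
            if n_common < min_common:
                failures.append((sets[i].dataset_id, sets[j].dataset_id,
                                 f"only {n_common} common indices"))
                D[i, j] = D[j, i] = sentinel
                continue
            va, vb = ia[idx_a], ib[idx_b]
            if quantity == "amplitude":
                va = np.sqrt(np.maximum(va, 0.0))
                vb = np.sqrt(np.maximum(vb, 0.0))
            va = va - va.mean()
            vb = vb - vb.mean()
            na, nb = np.linalg.norm(va), np.linalg.norm(vb)
            if na == 0 or nb == 0:
                failures.append((sets[i].dataset_id, sets[j].dataset_id,
                                 "zero variance"))
                D[i, j] = D[j, i] = sentinel
                continue
            cc = float(np.clip(np.dot(va / na, vb / nb), -1.0, 1.0))
            d = _base_distance(cc, base)
            f_unmatched = 1.0 - n_common / n_union
            if (1.0 - f_unmatched) < activation_threshold:
                d += penalty_weight * f_unmatched
            D[i, j] = D[j, i] = d
    return D, failures
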