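"""Pairwise distance matrices over species.

Two matrix flavours are used throughout:

* **absolute** distances ``|v_i - v_j|`` — symmetric, non-negative, the usual
  dissimilarity notion;
* **hierarchical** (signed) distances ``v_i - v_j`` — anti-symmetric, keeping
  the *direction* of the difference along a gradient.

Both are NA-aware: a pair involving a species with a missing value is NA, and
NA cells are deleted pairwise at vectorization time, never species-wise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "SymmetricDistanceMatrix",
    "SignedDistanceMatrix",
    "absolute_matrix",
    "hierarchical_matrix",
    "vectorize",
]


class _DistanceMatrix:
    """Species-labelled square matrix backed by a float ndarray."""

    signed = False

    def __init__(self, values, species):
        arr = np.asarray(values, dtype=float)
        species = list(species)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValidationError("distance matrix must be square")
        if arr.shape[0] != len(species):
            raise ValidationError("species labels do not match matrix size")
        if len(set(species)) != len(species):
            raise ValidationError("duplicate species identifiers")
        diag = np.diag(arr)
        if not np.allclose(diag[np.isfinite(diag)], 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        self._validate_pairing(arr)
        np.fill_diagonal(arr, 0.0)
        self.values = arr
        self.species = species

    def _validate_pairing(self, arr):
        off = ~np.eye(arr.shape[0], dtype=bool)
        a, b = arr[off], arr.T[off]
        na_a, na_b = np.isnan(a), np.isnan(b)
        if not np.array_equal(na_a, na_b):
            raise ValidationError("NA cells must be placed symmetrically")
        ok = ~na_a
        rel = self._pair_residual(a[ok], b[ok])
        if rel.size and np.max(np.abs(rel)) > 1e-9:
            kind = "anti-symmetric" if self.signed else "symmetric"
            raise ValidationError(f"matrix is not {kind}")

    def _pair_residual(self, a, b):
        return a - b

    @property
    def n_species(self):
        return len(self.species)

    def to_frame(self):
        return pd.DataFrame(self.values, index=self.species, columns=self.species)

    def to_csv(self, path, na_rep="NA"):
        self.to_frame().to_csv(path, na_rep=na_rep)

    @classmethod
    def from_frame(cls, frame):
        return cls(frame.to_numpy(dtype=float), list(frame.index))

    @classmethod
    def read_csv(cls, path):
        frame = pd.read_csv(path, index_col=0, na_values=["NA"])
        return cls.from_frame(frame)

    def reindex(self, species):
        """Return a copy with rows/columns reordered to ``species``."""
        missing = set(species) - set(self.species)
        if missing:
            raise ValidationError(f"unknown species: {sorted(missing)}")
        idx = [self.species.index(s) for s in species]
        return type(self)(self.values[np.ix_(idx, idx)], list(species))

    def __repr__(self):  # pragma: no cover
        return f"{type(self).__name__}(n={self.n_species})"


class SymmetricDistanceMatrix(_DistanceMatrix):
    """Non-negative symmetric distances with a zero diagonal; NA allowed."""

    def _validate_pairing(self, arr):
        super()._validate_pairing(arr)
        off = arr[~np.eye(arr.shape[0], dtype=bool)]
        if np.any(off[np.isfinite(off)] < -1e-12):
            raise ValidationError("symmetric distances must be non-negative")


class SignedDistanceMatrix(_DistanceMatrix):
    """Anti-symmetric signed differences, M[i, j] = -M[j, i]."""

    signed = True

    def _pair_residual(self, a, b):
        return a + b


def _usable(values):
    v = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(v)) < 3:
        raise ValidationError(
            "need at least 3 species with non-NA values to build a distance matrix"
        )
    return v


def absolute_matrix(values: pd.Series) -> SymmetricDistanceMatrix:
    """Absolute pairwise distance matrix |v_i - v_j| from a species series."""
    v = _usable(values)
    m = np.abs(v[:, None] - v[None, :])
    return SymmetricDistanceMatrix(m, list(values.index))


def hierarchical_matrix(values: pd.Series) -> SignedDistanceMatrix:
    """Signed (hierarchical) pairwise difference matrix v_i - v_j."""
    v = _usable(values)
    m = v[:, None] - v[None, :]
    return SignedDistanceMatrix(m, list(values.index))


def pair_indices(n: int, mode: str):
    """Row/column index arrays of the pair ordering used by :func:`vectorize`.

    ``upper``: row-major upper triangle (i < j). ``all_offdiag``: row-major
    all off-diagonal cells. The ordering is deterministic so that two
    matrices over the same species vectorize into aligned vectors.
    """
    if mode == "upper":
        iu, ju = np.triu_indices(n, k=1)
    elif mode == "all_offdiag":
        grid = ~np.eye(n, dtype=bool)
        iu, ju = np.nonzero(grid)
    else:
        raise ValueError(f"unknown vectorization mode: {mode!r}")
    return iu, ju


def vectorize(matrix, mode="upper", mask=None):
    """Flatten a distance matrix into an aligned pair vector.

    Parameters
    ----------
    matrix : SymmetricDistanceMatrix | SignedDistanceMatrix
    mode : {'upper', 'all_offdiag'}
    mask : optional boolean array over pairs (in this ordering) selecting a
        subset; used to align two matrices on their joint complete pairs.

    Returns
    -------
    values : float ndarray (NA pairs removed)
    pairs : list of (i, j) index tuples retained, aligned with ``values``
    """
    iu, ju = pair_indices(matrix.n_species, mode)
    vals = matrix.values[iu, ju]
    keep = np.isfinite(vals)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if mode == "upper":
        n_pairs = int(keep.sum())
    else:
        n_pairs = int(keep.sum()) // 2
    if n_pairs < 3:
        raise ValidationError("fewer than 3 complete pairs after NA masking")
    pairs = list(zip(iu[keep].tolist(), ju[keep].tolist()))
    return vals[keep], pairs
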