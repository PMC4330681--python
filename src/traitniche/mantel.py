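"""Mantel statistic and permutation test for distance matrices.

The Mantel statistic is the Pearson correlation between the pair vectors of
two species-aligned distance matrices. Its null distribution is generated by
jointly permuting the rows and columns of one matrix (a random relabelling of
species), which preserves the matrix's internal structure — symmetry for
ordinary distances, anti-symmetry for signed (hierarchical) differences.

Signed matrices are always vectorized over *all* off-diagonal cells: each
pair contributes +d and -d, so the pair vector has exact zero mean and the
statistic is invariant to species input order (the upper triangle alone is
not, for anti-symmetric matrices).

The p-value uses the add-one rule ``(1 + #extreme) / (n_perm + 1)``, so it is
never zero. For n <= 8 species :func:`mantel_exact` enumerates all n!
relabellings and returns the exact permutation p.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .distances import pair_indices
from .errors import UndefinedStatisticError, ValidationError

__all__ = ["MantelResult", "mantel_r", "mantel_test", "mantel_exact"]

_TIE_EPS = 1e-12
_VAR_EPS = 1e-30


@dataclass(frozen=True)
class MantelResult:
    """Outcome of a Mantel permutation test."""

    r: float
    p: float
    tail: str
    n_permutations: int
    n_pairs_used: int
    seed: int | None = None
    method: str = "monte_carlo"

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Mantel r outside [-1, 1]")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")


def _resolve_mode_tail(x, y, mode, tail):
    signed = x.signed or y.signed
    if signed:
        if mode not in (None, "all_offdiag"):
            raise ValidationError(
                "signed (hierarchical) matrices require all_offdiag vectorization"
            )
        mode = "all_offdiag"
    elif mode is None:
        mode = "upper"
    if tail is None:
        # hierarchical hypotheses are direction-aware (two-sided); absolute
        # distance hypotheses test for a more-positive-than-chance correlation
        tail = "two_sided" if signed else "greater"
    if tail not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown tail: {tail!r}")
    return mode, tail


def _aligned_pair_values(x, y, mode):
    if set(x.species) != set(y.species):
        raise ValidationError("matrices must share the same species set")
    y = y.reindex(x.species)
    iu, ju = pair_indices(x.n_species, mode)
    return x.values[iu, ju], y.values, iu, ju


def _pearson(a, b):
    va = a - a.mean()
    vb = b - b.mean()
    den = math.sqrt(float(va @ va) * float(vb @ vb))
    if den < _VAR_EPS:
        raise UndefinedStatisticError("zero variance in a pair vector")
    return max(-1.0, min(1.0, float(va @ vb) / den))


def _n_pairs(keep, mode):
    n = int(np.sum(keep))
    return n if mode == "upper" else n // 2


def mantel_r(x, y, mode=None):
    """Observed Mantel statistic between two aligned distance matrices.

    NA pairs (in either matrix) are deleted pairwise. Raises
    :class:`UndefinedStatisticError` if a pair vector is constant.
    """
    mode, _ = _resolve_mode_tail(x, y, mode, None)
    xv, yvals, iu, ju = _aligned_pair_values(x, y, mode)
    yv = yvals[iu, ju]
    keep = np.isfinite(xv) & np.isfinite(yv)
    if _n_pairs(keep, mode) < 3:
        raise ValidationError("fewer than 3 complete pairs after NA masking")
    return _pearson(xv[keep], yv[keep])


def _permuted_r(xv, yvals, iu, ju, perms, mode):
    """Mantel r for a (n_perm, n) array of relabellings, NA-aware, vectorized."""
    min_cnt = 3 if mode == "upper" else 6
    yp = yvals[perms[:, iu], perms[:, ju]]
    valid = np.isfinite(yp) & np.isfinite(xv)[None, :]
    cnt = valid.sum(axis=1).astype(float)
    xw = np.where(valid, xv[None, :], 0.0)
    yw = np.where(valid, yp, 0.0)
    mx = xw.sum(axis=1) / cnt
    my = yw.sum(axis=1) / cnt
    cov = (xw * yw).sum(axis=1) / cnt - mx * my
    vx = (xw * xw).sum(axis=1) / cnt - mx * mx
    vy = (yw * yw).sum(axis=1) / cnt - my * my
    den = vx * vy
    degenerate = (den < _VAR_EPS) | (cnt < min_cnt)  # < 3 unordered pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(den)
    return r, degenerate


def _tail_count(r_perm, r_obs, tail):
    if tail == "greater":
        return int(np.sum(r_perm >= r_obs - _TIE_EPS))
    if tail == "less":
        return int(np.sum(r_perm <= r_obs + _TIE_EPS))
    return int(np.sum(np.abs(r_perm) >= abs(r_obs) - _TIE_EPS))


def mantel_test(x, y, n_perm=999, tail=None, seed=None, mode=None) -> MantelResult:
    """Monte-Carlo Mantel test with ``n_perm`` random species relabellings.

    The relabelling is applied to the rows *and* columns of ``y`` (equivalent
    in distribution to permuting ``x``); NA masking is re-applied per
    permutation. Reproducible under a fixed ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mode, tail = _resolve_mode_tail(x, y, mode, tail)
    xv, yvals, iu, ju = _aligned_pair_values(x, y, mode)
    yv = yvals[iu, ju]
    keep = np.isfinite(xv) & np.isfinite(yv)
    n_pairs = _n_pairs(keep, mode)
    if n_pairs < 3:
        raise ValidationError("fewer than 3 complete pairs after NA masking")
    r_obs = _pearson(xv[keep], yv[keep])

    rng = np.random.default_rng(seed)
    n = x.n_species
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    r_perm, degenerate = _permuted_r(xv, yvals, iu, ju, perms, mode)
    r_perm = r_perm[~degenerate]
    if r_perm.size == 0:
        raise UndefinedStatisticError("all permutations degenerate")
    p = (1 + _tail_count(r_perm, r_obs, tail)) / (r_perm.size + 1)
    return MantelResult(r=r_obs, p=p, tail=tail, n_permutations=int(r_perm.size),
                        n_pairs_used=n_pairs, seed=seed)


def mantel_exact(x, y, tail=None, mode=None) -> MantelResult:
    """Exact Mantel test enumerating all n! species relabellings (n <= 8)."""
    n = x.n_species
    if n > 8:
        raise ValidationError("exact enumeration limited to 8 species (n! growth)")
    mode, tail = _resolve_mode_tail(x, y, mode, tail)
    xv, yvals, iu, ju = _aligned_pair_values(x, y, mode)
    yv = yvals[iu, ju]
    keep = np.isfinite(xv) & np.isfinite(yv)
    n_pairs = _n_pairs(keep, mode)
    if n_pairs < 3:
        raise ValidationError("fewer than 3 complete pairs after NA masking")
    r_obs = _pearson(xv[keep], yv[keep])

    perms = np.array(list(itertools.permutations(range(n))))
    r_perm, degenerate = _permuted_r(xv, yvals, iu, ju, perms, mode)
    r_perm = r_perm[~degenerate]
    if r_perm.size == 0:
        raise UndefinedStatisticError("all permutations degenerate")
    p = _tail_count(r_perm, r_obs, tail) / r_perm.size
    return MantelResult(r=r_obs, p=p, tail=tail, n_permutations=int(r_perm.size),
                        n_pairs_used=n_pairs, seed=None, method="exact")
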