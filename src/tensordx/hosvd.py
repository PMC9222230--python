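"""Higher-order singular value decomposition (HOSVD / Tucker).

An N-mode tensor x is expanded as

    x = G x_1 U1 x_2 U2 ... x_N UN

where Un holds the left singular vectors of the mode-n unfolding of x
(columns ordered by descending singular value) and the core G is x
contracted with every Un transpose.  At full rank the expansion is exact
and ||G||_F = ||x||_F.

Sign convention: each factor column is flipped so that its
largest-magnitude entry is positive, making the decomposition
deterministic (SVD is sign-ambiguous per singular vector).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding: mode ``mode`` as rows, all other modes flattened as columns."""
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def mode_dot(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Contract ``matrix`` (r x I_mode) against ``tensor`` along ``mode``."""
    out = np.tensordot(matrix, tensor, axes=(1, mode))
    return np.moveaxis(out, 0, mode)


def _fix_signs(u: np.ndarray) -> np.ndarray:
    if u.size == 0:
        return u
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


@dataclass
class TuckerDecomposition:
    """Core tensor plus one column-orthonormal factor matrix per mode."""

    core: np.ndarray
    factors: list[np.ndarray]
    mode_names: tuple[str, ...] | None = None

    @property
    def n_modes(self) -> int:
        return len(self.factors)

    def factor(self, mode: int | str) -> np.ndarray:
        return self.factors[self.mode_index(mode)]

    def mode_index(self, mode: int | str) -> int:
        if isinstance(mode, str):
            if self.mode_names is None:
                raise ValueError("decomposition has no mode names")
            return self.mode_names.index(mode)
        return mode


def hosvd(tensor: np.ndarray,
          rank_per_mode: Sequence[int] | None = None,
          mode_names: Sequence[str] | None = None) -> TuckerDecomposition:
    """Compute the HOSVD of ``tensor``.

    Parameters
    ----------
    tensor
        Real array with at least 2 modes.
    rank_per_mode
        Retained columns per mode; defaults to the economy rank
        min(mode size, product of other mode sizes).
    mode_names
        Optional axis labels carried into the decomposition.
    """
    x = np.asarray(tensor, dtype=float)
    if x.ndim < 2:
        raise ValueError(f"tensor must have >= 2 modes, got {x.ndim}")
    if rank_per_mode is not None:
        if len(rank_per_mode) != x.ndim:
            raise ValueError("rank_per_mode length must equal number of modes")
        for n, r in enumerate(rank_per_mode):
            if not 1 <= r <= x.shape[n]:
                raise ValueError(
                    f"rank {r} for mode {n} outside [1, {x.shape[n]}]")
    factors = []
    for n in range(x.ndim):
        m = unfold(x, n)
        u, _, _ = np.linalg.svd(m, full_matrices=False)
        if rank_per_mode is not None:
            u = u[:, :rank_per_mode[n]]
        factors.append(_fix_signs(u))
    core = x
    for n, u in enumerate(factors):
        core = mode_dot(core, u.T, n)
    names = tuple(mode_names) if mode_names is not None else None
    return TuckerDecomposition(core=core, factors=factors, mode_names=names)


def reconstruct(decomposition: TuckerDecomposition) -> np.ndarray:
    """Contract the core with all factors: the inverse of :func:`hosvd` at full rank."""
    out = decomposition.core
    if out.ndim != len(decomposition.factors):
        raise ValueError("core order does not match number of factors")
    for n, u in enumerate(decomposition.factors):
        if u.shape[1] != out.shape[n]:
            raise ValueError(
                f"factor for mode {n} has {u.shape[1]} columns, core has "
                f"{out.shape[n]}")
        out = mode_dot(out, u, n)
    return out
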