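"""The universal count-data container.

Every estimator in lgpois consumes a :class:`CountDataset`: a count
response ``y``, a known positive offset ``z`` (e.g. population at risk,
entering the mean as a multiplier), a fixed-effects design matrix ``X``,
and optionally categorical group labels and 2-D planar coordinates for
random-effect terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["CountDataset"]


def _as_1d_float(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class CountDataset:
    """Count response with offsets, covariates and optional random-effect info.

    Parameters
    ----------
    y
        Non-negative integer counts, length N.
    X
        N x K design matrix of covariates. The first column is
        conventionally an intercept of ones; ``CountDataset`` does not
        add one for you.
    z
        Positive offsets, length N. Defaults to all ones.
    groups
        Optional list of (name, labels) pairs; each ``labels`` is a
        length-N vector of categorical labels for one group-wise random
        intercept.
    coords
        Optional N x 2 planar coordinates for a spatial random effect.
    """

    y: np.ndarray
    X: np.ndarray
    z: np.ndarray | None = None
    groups: list[tuple[str, np.ndarray]] = field(default_factory=list)
    coords: np.ndarray | None = None

    def __post_init__(self):
        self.y = _as_1d_float(self.y, "y")
        n = self.y.size
        if n == 0:
            raise InvalidInputError("y must be non-empty")
        if np.any(self.y < 0) or not np.all(np.isfinite(self.y)):
            raise InvalidInputError("counts must be finite and non-negative")
        if np.any(self.y != np.round(self.y)):
            raise InvalidInputError("counts must be integer-valued")
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != n:
            raise InvalidInputError(
                f"X has {self.X.shape[0]} rows but y has {n} entries"
            )
        if self.X.shape[1] > n:
            raise InvalidInputError("more covariates than observations")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise InvalidInputError("X is rank-deficient")
        if self.z is None:
            self.z = np.ones(n)
        else:
            self.z = _as_1d_float(self.z, "z")
            if self.z.size != n:
                raise InvalidInputError("z must have the same length as y")
            if np.any(self.z <= 0) or not np.all(np.isfinite(self.z)):
                raise InvalidInputError("offsets must be positive and finite")
        self.groups = [(str(name), np.asarray(g)) for name, g in self.groups]
        for name, g in self.groups:
            if g.shape != (n,):
                raise InvalidInputError(f"group labels {name!r} must have length {n}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2):
                raise InvalidInputError("coords must be an N x 2 array")
            if not np.all(np.isfinite(self.coords)):
                raise InvalidInputError("coords must be finite")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def k(self) -> int:
        return self.X.shape[1]
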