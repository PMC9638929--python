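"""Peak-volume vectors.

A polysome profile, once decomposed into peaks, reduces to a mapping from
peak index to the fraction of total signal carried by that peak.  Peak
indices follow gradient convention: fractional indices for the free
ribosomal subunits (the small subunit at its mass fraction of a full
ribosome, e.g. 0.35 in yeast; the large subunit at one minus that), 1 for
the monosome, and integers >= 2 for the n-somes.  These normalized vectors
are the common currency for comparing, clustering and rendering profiles.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np

from .errors import DomainError, InvalidInputError

#: decimal places used to canonicalise float peak indices as dict keys
_INDEX_DECIMALS = 6


def canon_index(index: float) -> float:
    """Round a peak index to the canonical key resolution; must be > 0."""
    value = round(float(index), _INDEX_DECIMALS)
    if not value > 0:
        raise DomainError(f"peak index must be > 0, got {index!r}")
    return value


class PeakVolumes(Mapping):
    """Immutable mapping of peak index -> non-negative volume.

    Volumes need not sum to one on construction; :meth:`normalized` returns
    a rescaled copy and :meth:`is_normalized` tests the unit-sum invariant
    that comparison operations require.
    """

    __slots__ = ("_v",)

    def __init__(self, volumes: Mapping[float, float] | Iterable[tuple[float, float]]):
        items: dict[float, float] = {}
        for key, value in dict(volumes).items():
            key = canon_index(key)
            value = float(value)
            if not np.isfinite(value) or value < 0:
                raise InvalidInputError(
                    f"volume for peak {key} must be finite and >= 0, got {value!r}"
                )
            items[key] = items.get(key, 0.0) + value
        self._v = dict(sorted(items.items()))

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, index: float) -> float:
        return self._v[canon_index(index)]

    def __iter__(self):
        return iter(self._v)

    def __len__(self) -> int:
        return len(self._v)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = ", ".join(f"{k:g}: {v:.4g}" for k, v in self._v.items())
        return f"PeakVolumes({{{body}}})"

    # ----------------------------------------------------------------------
    @property
    def indices(self) -> np.ndarray:
        """Sorted peak indices."""
        return np.array(list(self._v), dtype=float)

    @property
    def values_array(self) -> np.ndarray:
        """Volumes in index order."""
        return np.array(list(self._v.values()), dtype=float)

    def total(self) -> float:
        return float(sum(self._v.values()))

    def is_normalized(self, tol: float = 1e-6) -> bool:
        return abs(self.total() - 1.0) <= tol

    def normalized(self) -> "PeakVolumes":
        total = self.total()
        if total <= 0:
            raise InvalidInputError("cannot normalize a zero-mass volume vector")
        return PeakVolumes({k: v / total for k, v in self._v.items()})

    def get(self, index: float, default: float = 0.0) -> float:
        return self._v.get(canon_index(index), default)


def align(vectors: Iterable[PeakVolumes]) -> tuple[np.ndarray, np.ndarray]:
    """Align volume vectors on the union of their peak indices.

    Missing peaks read as zero volume.  Returns ``(indices, matrix)`` with
    ``matrix[i, j]`` the volume of vector ``i`` at ``indices[j]``.
    """
    vectors = list(vectors)
    if not vectors:
        raise InvalidInputError("no volume vectors to align")
    union = sorted({k for v in vectors for k in v})
    matrix = np.zeros((len(vectors), len(union)))
    for i, vec in enumerate(vectors):
        for j, idx in enumerate(union):
            matrix[i, j] = vec.get(idx, 0.0)
    return np.array(union, dtype=float), matrix
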