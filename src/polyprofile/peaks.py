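"""Peak detection and the logarithmic peak-location model.

In a sucrose density gradient, transcripts carrying more ribosomes sediment
deeper, but the spacing between successive n-some peaks shrinks with n: in
well-formed gradients the position of the n-th peak is well described by

    position(n) = a * ln(n) + b

with a > 0.  The free ribosomal subunits appear at fractional indices
(small subunit at its mass fraction of a full ribosome, large subunit at the
complement), so a single curve covers 40S, 60S, 80S and all n-somes.  A fit
through a handful of clearly resolved peaks extrapolates peak positions into
the compressed high-polysome region where peaks are no longer separable by
eye.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InsufficientDataError, InvalidInputError
from .volumes import canon_index

#: small-subunit mass fraction of a full ribosome, by taxon
SMALL_SUBUNIT_FRACTION = {"yeast": 0.35, "mammal": 0.37}


def subunit_indices(small_fraction: float) -> tuple[float, float]:
    """Fractional peak indices (small, large) for free ribosomal subunits.

    The small subunit sediments at its mass fraction of a monosome; the
    large subunit at the complementary fraction.
    """
    if not 0 < small_fraction < 1:
        raise InvalidInputError("small-subunit fraction must be in (0, 1)")
    return small_fraction, 1.0 - small_fraction


@dataclass(frozen=True)
class ProfileTrace:
    """One gradient scan: OD254 absorbance sampled along the gradient axis.

    Positions are in arbitrary units (sample index, mm, ...) and must be
    strictly increasing; absorbances must be finite (small negative values
    are tolerated — baseline handling happens downstream).
    """

    position: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        absn = np.asarray(self.absorbance, dtype=float)
        if pos.ndim != 1 or absn.ndim != 1 or pos.size != absn.size:
            raise InvalidInputError("position and absorbance must be 1-D and equal length")
        if pos.size < 20:
            raise InvalidInputError(f"trace needs >= 20 samples, got {pos.size}")
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(absn)):
            raise InvalidInputError("trace contains non-finite values")
        if not np.all(np.diff(pos) > 0):
            bad = int(np.flatnonzero(np.diff(pos) <= 0)[0]) + 1
            raise InvalidInputError(f"positions not strictly increasing at row {bad}")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "absorbance", absn)

    def __len__(self) -> int:
        return self.position.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.position[0]), float(self.position[-1])


@dataclass(frozen=True)
class PeakLocationModel:
    """position = a * ln(index) + b, fitted over ``index_domain``.

    ``rms_residual`` is the root-mean-square residual of the fit in gradient
    units.  a > 0 guarantees positions strictly increasing and inter-peak
    spacing strictly decreasing in index (logarithmic compression).
    """

    a: float
    b: float
    index_domain: tuple[float, ...] = field(default_factory=tuple)
    rms_residual: float = 0.0

    def __post_init__(self):
        if not self.a > 0:
            raise InvalidInputError(f"location-model slope must be > 0, got {self.a}")

    def predict(self, indices) -> np.ndarray:
        return predict_positions(self, indices)


def detect_peaks(trace: ProfileTrace, min_run: int = 4) -> np.ndarray:
    """Find local maxima flanked by long monotonic runs.

    A sample is a peak when it terminates a run of ``min_run`` strictly
    increasing points and starts a run of ``min_run`` strictly decreasing
    points (the peak sample counts toward both runs).  Ties break a run.
    Returns peak *positions* in increasing order; an empty array when no
    peak qualifies.
    """
    if min_run < 2:
        raise InvalidInputError(f"min_run must be >= 2, got {min_run}")
    if len(trace) < 2 * min_run:
        raise InvalidInputError(
            f"trace of {len(trace)} samples too short for min_run={min_run}"
        )
    y = trace.absorbance
    n = y.size
    # run lengths in points: inc[i] = length of strictly-increasing run ending at i
    inc = np.ones(n, dtype=int)
    for i in range(1, n):
        if y[i] > y[i - 1]:
            inc[i] = inc[i - 1] + 1
    dec = np.ones(n, dtype=int)
    for i in range(n - 2, -1, -1):
        if y[i] > y[i + 1]:
            dec[i] = dec[i + 1] + 1
    hits = np.flatnonzero((inc >= min_run) & (dec >= min_run))
    return trace.position[hits]


def fit_location_model(peak_positions, peak_indices) -> PeakLocationModel:
    """Least-squares fit of position = a·ln(index) + b.

    Requires >= 3 (position, index) pairs with strictly increasing indices
    and positions.  Fractional subunit indices participate like any other
    point; the model is index-agnostic.
    """
    pos = np.asarray(peak_positions, dtype=float)
    idx = np.asarray([canon_index(i) for i in np.atleast_1d(peak_indices)], dtype=float)
    if pos.size != idx.size:
        raise InvalidInputError("positions and indices differ in length")
    if pos.size < 3:
        raise InsufficientDataError(f"need >= 3 peaks to fit, got {pos.size}")
    if not np.all(np.diff(idx) > 0):
        raise InvalidInputError("peak indices must be strictly increasing")
    if not np.all(np.diff(pos) > 0):
        raise InvalidInputError("peak positions must be strictly increasing")
    x = np.log(idx)
    a, b = np.polyfit(x, pos, 1)
    resid = pos - (a * x + b)
    rms = float(np.sqrt(np.mean(resid**2)))
    return PeakLocationModel(a=float(a), b=float(b),
                             index_domain=tuple(idx), rms_residual=rms)


def predict_positions(model: PeakLocationModel, indices) -> np.ndarray:
    """Positions a·ln(index) + b; strictly increasing for increasing indices."""
    idx = np.asarray(np.atleast_1d(indices), dtype=float)
    if np.any(idx <= 0):
        raise DomainError("peak indices must be > 0")
    return model.a * np.log(idx) + model.b


def assign_default_indices(
    peak_positions, start_position: float = -np.inf
) -> tuple[np.ndarray, np.ndarray]:
    """Index detected peaks 1, 2, 3, ... past a debris cutoff.

    The debris region at the top of the gradient produces spurious maxima;
    ``start_position`` discards everything before it.  The remaining peaks
    are assumed to start at the monosome.  Supply explicit indices to
    :func:`fit_location_model` instead when subunit peaks were detected.
    """
    pos = np.asarray(peak_positions, dtype=float)
    keep = pos[pos >= start_position]
    return keep, np.arange(1, keep.size + 1, dtype=float)
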