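"""Constrained Gaussian-mixture representation of a polysome profile.

Each peak is a scaled normal probability density

    f(x | mu, sigma, s) = s / sqrt(2 pi sigma^2) * exp(-(x - mu)^2 / (2 sigma^2))

so the scaling factor s is exactly the area under the peak; after
normalisation the s values are the peak-volume vector.  The full profile
adds an exponential debris term A·exp(-k·x) for light cellular material at
the top of the gradient and a linear baseline m·x + c for detector drift.

Unlike a free Gaussian mixture, peak centres mu are FIXED at positions from
the logarithmic location model: in the compressed high-polysome region free
means are not identifiable, while fixed means leave a well-conditioned
problem in the scales, widths and background.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateProfileError,
    FitFailureError,
    InvalidInputError,
    UndefinedRatioError,
)
from .peaks import ProfileTrace
from .volumes import PeakVolumes, canon_index

log = logging.getLogger(__name__)

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class GaussianPeak:
    """One profile peak: scaled normal PDF at a fixed gradient position."""

    index: float
    mu: float
    sigma: float
    s: float

    def __post_init__(self):
        object.__setattr__(self, "index", canon_index(self.index))
        if not self.sigma > 0:
            raise InvalidInputError(f"sigma must be > 0, got {self.sigma}")
        if self.s < 0:
            raise InvalidInputError(f"peak scale must be >= 0, got {self.s}")


@dataclass(frozen=True)
class DebrisBaseline:
    """Background: debris decay A·exp(-k·x) plus linear baseline m·x + c."""

    amplitude: float = 0.0
    decay: float = 1.0
    slope: float = 0.0
    offset: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise InvalidInputError("debris amplitude must be >= 0")
        if not self.decay > 0:
            raise InvalidInputError("debris decay rate must be > 0")

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.amplitude * np.exp(-self.decay * x) + self.slope * x + self.offset


@dataclass
class ProfileModel:
    """A set of scaled Gaussian peaks plus a debris/baseline background."""

    peaks: list[GaussianPeak]
    background: DebrisBaseline = field(default_factory=DebrisBaseline)
    rms_error: float | None = None

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.index)
        mus = [p.mu for p in self.peaks]
        if any(b <= a for a, b in zip(mus, mus[1:])):
            raise InvalidInputError("peak centres must increase strictly with index")


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (_SQRT2PI * sigma)


def evaluate_model(model: ProfileModel, positions) -> np.ndarray:
    """Pointwise sum of all scaled peaks and the background."""
    x = np.asarray(positions, dtype=float)
    y = model.background(x)
    for p in model.peaks:
        y = y + p.s * _gauss(x, p.mu, p.sigma)
    return y


def local_spacings(mus: np.ndarray) -> np.ndarray:
    """Local inter-peak distance per peak (central difference, one-sided ends).

    For a single peak there is no spacing; callers must supply a width scale.
    """
    mus = np.asarray(mus, dtype=float)
    if mus.size < 2:
        raise InvalidInputError("need >= 2 peak positions for local spacings")
    spac = np.empty_like(mus)
    spac[1:-1] = (mus[2:] - mus[:-2]) / 2.0
    spac[0] = mus[1] - mus[0]
    spac[-1] = mus[-1] - mus[-2]
    return spac


def fit_profile(
    trace: ProfileTrace,
    locations: dict[float, float],
    *,
    shared_width: bool = True,
    width_bounds: tuple[float, float] = (1e-3, 1.0),
    out_of_range: str = "error",
    tol: float = 1e-10,
    max_nfev: int = 5000,
) -> ProfileModel:
    """Fit peak scales, widths and background to a trace at fixed peak centres.

    Parameters
    ----------
    locations
        Mapping peak index -> centre position, typically from the location
        model.  Centres are held fixed throughout the fit.
    shared_width
        When True (default) all widths are tied as sigma_i = w * spacing_i
        with a single fitted factor w in ``width_bounds``; the local
        spacing shrinks logarithmically with index, so tied widths track the
        gradient compression and keep the high-n tail identifiable.  When
        False each sigma_i is free within ``width_bounds`` times its local
        spacing.
    out_of_range
        "error" rejects centres outside the trace span; "drop" discards them
        with a warning.

    Returns the fitted :class:`ProfileModel` with ``rms_error`` set.
    """
    items = sorted(((canon_index(i), float(m)) for i, m in locations.items()),
                   key=lambda t: t[0])
    lo, hi = trace.span
    inside = [(i, m) for i, m in items if lo <= m <= hi]
    if len(inside) < len(items):
        dropped = [i for i, m in items if not lo <= m <= hi]
        if out_of_range == "drop":
            log.warning("dropping %d peak(s) outside trace range: %s",
                        len(dropped), dropped)
        else:
            raise InvalidInputError(
                f"peak centres outside trace range {trace.span}: {dropped}")
    if len(inside) < 3:
        raise InvalidInputError(f"need >= 3 peak locations inside the trace, got {len(inside)}")

    indices = np.array([i for i, _ in inside])
    mus = np.array([m for _, m in inside])
    spacings = local_spacings(mus)
    x, y = trace.position, trace.absorbance
    npk = mus.size
    span = hi - lo

    # initial scales: trapezoidal signal mass within +-spacing/2 of each centre
    base0 = float(np.percentile(y, 5))
    s0 = np.empty(npk)
    for j in range(npk):
        sel = (x >= mus[j] - spacings[j] / 2) & (x <= mus[j] + spacings[j] / 2)
        if sel.sum() >= 2:
            s0[j] = max(np.trapezoid(np.clip(y[sel] - base0, 0, None), x[sel]), 1e-12)
        else:
            s0[j] = 1e-12
    w0 = 0.25
    a0 = max(float(y[0] - base0), 1e-12)
    k0 = 5.0 / max(mus[0] - lo, span / 20)
    m0, c0 = 0.0, base0

    nwidth = 1 if shared_width else npk
    theta0 = np.concatenate([s0, np.full(nwidth, w0), [a0, k0, m0, c0]])
    lower = np.concatenate([np.zeros(npk), np.full(nwidth, width_bounds[0]),
                            [0.0, 1e-6, -np.inf, -np.inf]])
    upper = np.concatenate([np.full(npk, np.inf), np.full(nwidth, width_bounds[1]),
                            [np.inf, np.inf, np.inf, np.inf]])

    def unpack(theta):
        s = theta[:npk]
        w = theta[npk:npk + nwidth]
        amp, dec, slope, off = theta[npk + nwidth:]
        sigmas = (w[0] if shared_width else w) * spacings
        return s, sigmas, amp, dec, slope, off

    def residuals(theta):
        s, sigmas, amp, dec, slope, off = unpack(theta)
        model = amp * np.exp(-dec * x) + slope * x + off
        for j in range(npk):
            model = model + s[j] * _gauss(x, mus[j], sigmas[j])
        return model - y

    result = least_squares(residuals, theta0, bounds=(lower, upper),
                           ftol=tol, xtol=tol, gtol=tol,
                           max_nfev=max_nfev, x_scale="jac")
    rms = float(np.sqrt(np.mean(result.fun**2)))
    if result.status <= 0:
        raise FitFailureError(
            f"profile fit did not converge ({result.message})", last_residual=rms)

    s, sigmas, amp, dec, slope, off = unpack(result.x)
    peaks = [GaussianPeak(index=indices[j], mu=float(mus[j]),
                          sigma=float(sigmas[j]), s=float(s[j]))
             for j in range(npk)]
    background = DebrisBaseline(amplitude=float(amp), decay=float(dec),
                                slope=float(slope), offset=float(off))
    return ProfileModel(peaks=peaks, background=background, rms_error=rms)


def peak_volumes(model: ProfileModel) -> PeakVolumes:
    """Normalized per-peak signal fractions s_i / sum(s); background excluded.

    The area under an unscaled normal PDF is one, so each fitted scale is
    exactly the area of its peak and the normalized scales are the fractional
    contributions of the peaks to the profile.
    """
    total = sum(p.s for p in model.peaks)
    if total <= 0:
        raise DegenerateProfileError("all peak scales are zero; volumes undefined")
    return PeakVolumes({p.index: p.s / total for p in model.peaks})


def pm_ratio(volumes: PeakVolumes) -> float:
    """Polysome/monosome ratio: volume at n-somes >= 2 over the monosome volume.

    Free-subunit (fractional-index) peaks are excluded from both terms.
    """
    mono = volumes.get(1.0, 0.0)
    poly_indices = [i for i in volumes if i >= 2 and abs(i - round(i)) < 1e-9]
    if not poly_indices or 1.0 not in volumes:
        raise InvalidInputError("need a monosome peak and at least one n-some >= 2")
    if mono == 0:
        raise UndefinedRatioError("monosome volume is zero; P/M ratio undefined")
    return sum(volumes[i] for i in poly_indices) / mono
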