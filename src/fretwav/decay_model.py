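"""Donor fluorescence decay models for TCSPC lifetime FRET analysis.

This module evaluates the model functions used to describe time-correlated
single photon counting (TCSPC) histograms of a FRET donor:

* a multi-exponential donor-only decay (local quenching of the dye),
* the FRET-quenched decay of a donor coupled to an acceptor whose
  inter-dye distance follows a Gaussian distribution ``p(R_DA)`` with mean
  ``<R_DA>`` and standard deviation ``sigma_DA``,
* the total model combining a FRET population, a donor-only fraction
  ``x_D0`` and a constant background, and
* convolution with a measured or synthetic instrument response function
  (IRF).

All curves are evaluated on a discrete :class:`TimeGrid` whose time stamps
are the nominal bin centers (16 ps bins by default, far below any lifetime,
so bin-center evaluation is indistinguishable from bin integration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "InvalidParameterError",
    "GridMismatchError",
    "TimeGrid",
    "ExponentialComponents",
    "GaussianDistanceDistribution",
    "FretDecayParams",
    "TCSPCHistogram",
    "IRFCurve",
    "evaluate_multiexponential",
    "transfer_efficiency",
    "fret_rate_factor",
    "gaussian_distance_pdf",
    "distance_integration_grid",
    "fret_quenched_decay",
    "total_donor_model",
    "convolve_with_irf",
    "gaussian_irf",
    "delta_irf",
    "amplitude_averaged_lifetime",
    "amplitude_averaged_lifetime_and_qy",
]


class InvalidParameterError(ValueError):
    """A physical model parameter is outside its admissible range."""


class GridMismatchError(ValueError):
    """Two histograms that must share a time grid do not."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform TCSPC microtime axis.

    Parameters
    ----------
    bin_width:
        Bin width in ns (default 0.016, i.e. 16 ps resolution).
    n_bins:
        Number of bins (>= 2).
    origin:
        Time stamp of the first bin center in ns.
    """

    bin_width: float = 0.016
    n_bins: int = 3125
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise InvalidParameterError("bin_width must be > 0")
        if self.n_bins < 2:
            raise InvalidParameterError("n_bins must be >= 2")

    @property
    def times(self) -> np.ndarray:
        """Bin-center time stamps in ns."""
        return self.origin + self.bin_width * np.arange(self.n_bins)

    @property
    def span(self) -> float:
        """Total extent of the grid in ns."""
        return self.bin_width * self.n_bins


@dataclass(frozen=True)
class ExponentialComponents:
    """Amplitudes and lifetimes of a multi-exponential decay.

    Amplitude fractions ``x_i`` must lie in (0, 1] and sum to one;
    lifetimes ``tau_i`` are in ns and strictly positive.
    """

    amplitudes: tuple[float, ...]
    lifetimes: tuple[float, ...]

    def __post_init__(self) -> None:
        x = np.asarray(self.amplitudes, dtype=float)
        tau = np.asarray(self.lifetimes, dtype=float)
        if x.shape != tau.shape or x.ndim != 1 or x.size == 0:
            raise InvalidParameterError("amplitudes and lifetimes must be matching 1-d tuples")
        if np.any(x <= 0) or np.any(x > 1):
            raise InvalidParameterError("amplitude fractions must be in (0, 1]")
        if abs(x.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("amplitude fractions must sum to 1 within 1e-9")
        if np.any(tau <= 0):
            raise InvalidParameterError("lifetimes must be > 0")
        object.__setattr__(self, "amplitudes", tuple(float(v) for v in x))
        object.__setattr__(self, "lifetimes", tuple(float(v) for v in tau))

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.amplitudes)

    @property
    def tau(self) -> np.ndarray:
        return np.asarray(self.lifetimes)


@dataclass(frozen=True)
class GaussianDistanceDistribution:
    """Gaussian inter-dye distance distribution p(R_DA).

    ``mean_R`` is the most probable inter-dye distance ``<R_DA>`` and
    ``sigma_R`` the amplitude of distance fluctuations ``sigma_DA``
    (both in Angstrom). ``sigma_R = 0`` denotes a delta distribution.
    """

    mean_R: float
    sigma_R: float

    def __post_init__(self) -> None:
        if self.mean_R <= 0:
            raise InvalidParameterError("mean_R must be > 0")
        if self.sigma_R < 0:
            raise InvalidParameterError("sigma_R must be >= 0")


@dataclass(frozen=True)
class FretDecayParams:
    """Full parameter set of the donor decay model.

    Combines the donor-only components (shared by the quenched and
    unquenched populations), the Gaussian distance distribution, the
    Forster radius ``R0`` (Angstrom), a donor-only molecule fraction
    ``x_D0``, the peak amplitude ``I0`` (counts) and a constant
    per-bin background ``BG`` (counts).
    """

    donor_components: ExponentialComponents
    distance: GaussianDistanceDistribution
    forster_radius: float
    donor_only_fraction: float = 0.0
    peak_amplitude: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.forster_radius <= 0:
            raise InvalidParameterError("forster_radius must be > 0")
        if not 0.0 <= self.donor_only_fraction <= 1.0:
            raise InvalidParameterError("donor_only_fraction must be in [0, 1]")
        if self.peak_amplitude <= 0:
            raise InvalidParameterError("peak_amplitude must be > 0")
        if self.background < 0:
            raise InvalidParameterError("background must be >= 0")

    def with_updates(self, **kwargs) -> "FretDecayParams":
        """Return a copy with scalar fit parameters replaced.

        Accepted keys: ``mean_R``, ``sigma_R``, ``x_D0``, ``I0``, ``BG``.
        """
        dist = self.distance
        if "mean_R" in kwargs or "sigma_R" in kwargs:
            dist = GaussianDistanceDistribution(
                mean_R=float(kwargs.pop("mean_R", dist.mean_R)),
                sigma_R=float(kwargs.pop("sigma_R", dist.sigma_R)),
            )
        mapping = {"x_D0": "donor_only_fraction", "I0": "peak_amplitude", "BG": "background"}
        updates = {mapping[k]: float(v) for k, v in kwargs.items() if k in mapping}
        unknown = set(kwargs) - set(mapping)
        if unknown:
            raise KeyError(f"unknown fit parameters: {sorted(unknown)}")
        return replace(self, distance=dist, **updates)

    def get(self, name: str) -> float:
        values = {
            "mean_R": self.distance.mean_R,
            "sigma_R": self.distance.sigma_R,
            "x_D0": self.donor_only_fraction,
            "I0": self.peak_amplitude,
            "BG": self.background,
        }
        return values[name]


@dataclass(frozen=True)
class TCSPCHistogram:
    """Counts (or expected counts for model curves) per microtime bin."""

    grid: TimeGrid
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (self.grid.n_bins,):
            raise GridMismatchError(
                f"counts length {counts.shape} does not match grid n_bins {self.grid.n_bins}"
            )
        if np.any(counts < 0):
            raise InvalidParameterError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.counts))


@dataclass(frozen=True)
class IRFCurve:
    """Instrument response function sampled on a :class:`TimeGrid`."""

    grid: TimeGrid
    values: np.ndarray = field(repr=False)
    fwhm: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.grid.n_bins,):
            raise GridMismatchError("IRF values do not match grid length")
        if np.any(values < 0):
            raise InvalidParameterError("IRF values must be non-negative")
        if values.sum() <= 0:
            raise InvalidParameterError("IRF must have positive total area")
        object.__setattr__(self, "values", values)

    @property
    def normalized(self) -> np.ndarray:
        """Area-normalized IRF kernel."""
        return self.values / self.values.sum()

    @property
    def is_delta(self) -> bool:
        """True when the IRF is a single-bin impulse (convolution is a no-op shift)."""
        return np.count_nonzero(self.values) == 1


def evaluate_multiexponential(
    components: ExponentialComponents, I0: float, grid: TimeGrid
) -> TCSPCHistogram:
    """Multi-exponential donor-only decay ``I0 * sum_i x_i exp(-t/tau_i)``."""
    if I0 <= 0:
        raise InvalidParameterError("I0 must be > 0")
    t = grid.times
    curve = I0 * np.sum(
        components.x[:, None] * np.exp(-t[None, :] / components.tau[:, None]), axis=0
    )
    return TCSPCHistogram(grid=grid, counts=curve)


def transfer_efficiency(R, R0: float):
    """FRET efficiency ``E = 1 / (1 + (R/R0)^6)``.

    Vectorized over ``R``; raises for non-positive distances.
    """
    R = np.asarray(R, dtype=float)
    if R0 <= 0:
        raise InvalidParameterError("R0 must be > 0")
    if np.any(R <= 0):
        raise InvalidParameterError("distance R must be > 0")
    out = 1.0 / (1.0 + (R / R0) ** 6)
    return float(out) if out.ndim == 0 else out


def fret_rate_factor(R, R0: float):
    """Rate enhancement ``1 + (R0/R)^6`` multiplying the donor decay rate."""
    R = np.asarray(R, dtype=float)
    if R0 <= 0:
        raise InvalidParameterError("R0 must be > 0")
    if np.any(R <= 0):
        raise InvalidParameterError("distance R must be > 0")
    out = 1.0 + (R0 / R) ** 6
    return float(out) if out.ndim == 0 else out


def gaussian_distance_pdf(dist: GaussianDistanceDistribution, R_values) -> np.ndarray:
    """Continuous Gaussian density of ``p(R_DA)`` at the given distances (1/Angstrom)."""
    if dist.sigma_R <= 0:
        raise InvalidParameterError("gaussian_distance_pdf requires sigma_R > 0")
    R = np.asarray(R_values, dtype=float)
    z = (R - dist.mean_R) / dist.sigma_R
    return np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * dist.sigma_R)


def distance_integration_grid(
    dist: GaussianDistanceDistribution,
    step: float = 0.25,
    n_sigma: float = 4.0,
    r_min: float = 1.0,
    renormalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete distances and weights for the distance average of the decay.

    The Gaussian is truncated to ``[<R> - n_sigma*sigma, <R> + n_sigma*sigma]``
    sampled with the given step (0.25 Angstrom by default) and the lower bound
    is clipped to ``r_min`` to keep the ``(R0/R)^6`` rate factor finite.  By
    default the truncated discrete weights are renormalized to unit mass so the
    donor-only fraction retains its exact meaning; ``renormalize=False`` keeps
    the raw (midpoint-rule) Gaussian mass instead.
    """
    if dist.sigma_R == 0:
        return np.array([dist.mean_R]), np.array([1.0])
    lo = max(dist.mean_R - n_sigma * dist.sigma_R, r_min)
    hi = dist.mean_R + n_sigma * dist.sigma_R
    if hi <= r_min:
        raise InvalidParameterError("distance integration interval lies entirely below r_min")
    # for very narrow distributions refine the step so the Gaussian is
    # always sampled by at least ~25 points across the interval
    step = min(step, (hi - lo) / 24.0)
    n = max(int(np.floor((hi - lo) / step)) + 1, 2)
    R = lo + step * np.arange(n)
    w = gaussian_distance_pdf(dist, R) * step
    if renormalize:
        w = w / w.sum()
    return R, w


def fret_quenched_decay(
    params: FretDecayParams,
    grid: TimeGrid,
    step: float = 0.25,
    renormalize: bool = True,
) -> TCSPCHistogram:
    """Distance-averaged FRET-quenched donor decay ``F_DA(t)`` (unit amplitude).

    Every donor lifetime component is quenched by FRET at each distance of
    the discretized Gaussian, ``exp(-(t/tau_i) * (1 + (R0/R)^6))``, and the
    resulting decays are averaged with the Gaussian weights.  For
    ``sigma_R = 0`` the single-distance closed form is used directly.
    """
    comp = params.donor_components
    R, w = distance_integration_grid(params.distance, step=step, renormalize=renormalize)
    rates_factor = fret_rate_factor(R, params.forster_radius)  # (nR,)
    t = grid.times
    # (n_comp, nR) decay rates; weights x_i * w_R
    k = rates_factor[None, :] / comp.tau[:, None]
    weights = (comp.x[:, None] * w[None, :]).ravel()
    curve = np.exp(-np.outer(t, k.ravel())) @ weights
    return TCSPCHistogram(grid=grid, counts=curve)


def total_donor_model(
    params: FretDecayParams,
    grid: TimeGrid,
    irf: IRFCurve | None = None,
    step: float = 0.25,
    renormalize: bool = True,
    periodic_wrap: bool = False,
) -> TCSPCHistogram:
    """Total donor model ``F(t) = I0[(1-x_D0) F_DA + x_D0 F_D0] + BG``.

    When an IRF is supplied the background-free mixture is convolved with the
    area-normalized IRF before the constant background is added.
    """
    f_da = fret_quenched_decay(params, grid, step=step, renormalize=renormalize).counts
    f_d0 = evaluate_multiexponential(params.donor_components, 1.0, grid).counts
    x0 = params.donor_only_fraction
    mix = params.peak_amplitude * ((1.0 - x0) * f_da + x0 * f_d0)
    if irf is not None and not irf.is_delta:
        mix = _convolve(mix, irf, grid, periodic_wrap)
    elif irf is not None:
        # delta IRF: pure shift to the impulse position
        shift = int(np.argmax(irf.values))
        mix = np.concatenate([np.zeros(shift), mix[: grid.n_bins - shift]])
    return TCSPCHistogram(grid=grid, counts=mix + params.background)


def _convolve(model: np.ndarray, irf: IRFCurve, grid: TimeGrid, periodic_wrap: bool) -> np.ndarray:
    from scipy.signal import fftconvolve

    full = fftconvolve(model, irf.normalized)
    out = full[: grid.n_bins]
    if periodic_wrap:
        period_bins = grid.n_bins
        tail = full[grid.n_bins :]
        # fold the spill-over back onto the start of the next laser period
        for start in range(0, tail.size, period_bins):
            seg = tail[start : start + period_bins]
            out[: seg.size] += seg
    return np.clip(out, 0.0, None)


def convolve_with_irf(
    model: TCSPCHistogram,
    irf: IRFCurve,
    background: float = 0.0,
    periodic_wrap: bool = False,
) -> TCSPCHistogram:
    """Discrete convolution of a model decay with an area-normalized IRF.

    The optional constant ``background`` (counts per bin) is added after the
    convolution.  With ``periodic_wrap`` the convolution tail beyond the grid
    is folded back to the start, emulating the periodic excitation of a pulsed
    laser whose period equals the grid span.
    """
    if model.grid != irf.grid:
        raise GridMismatchError("model and IRF must share the same time grid")
    if irf.is_delta and np.argmax(irf.values) == 0:
        out = model.counts.copy()
    else:
        out = _convolve(model.counts, irf, model.grid, periodic_wrap)
    return TCSPCHistogram(grid=model.grid, counts=out + background)


def gaussian_irf(grid: TimeGrid, fwhm: float, t0: float = 2.0) -> IRFCurve:
    """Synthetic Gaussian IRF with the given FWHM (ns) centered at ``t0``."""
    if fwhm <= 0:
        raise InvalidParameterError("fwhm must be > 0")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = grid.times
    values = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    return IRFCurve(grid=grid, values=values, fwhm=fwhm)


def delta_irf(grid: TimeGrid, bin_index: int = 0) -> IRFCurve:
    """Unit-impulse IRF (identity kernel when placed in bin 0)."""
    values = np.zeros(grid.n_bins)
    values[bin_index] = 1.0
    return IRFCurve(grid=grid, values=values, fwhm=0.0)


def amplitude_averaged_lifetime(components: ExponentialComponents) -> float:
    """Amplitude-averaged lifetime ``<tau> = sum_i x_i tau_i`` in ns."""
    return float(np.dot(components.x, components.tau))


def amplitude_averaged_lifetime_and_qy(
    components: ExponentialComponents, ref_lifetime: float, ref_qy: float
) -> tuple[float, float]:
    """Amplitude-averaged lifetime and the quantum yield scaled from a reference dye.

    ``phi = phi_ref * <tau> / tau_ref`` with the free-dye reference lifetime
    and quantum yield; used to obtain quantum yields of labeled constructs
    from their fitted lifetime components.
    """
    if ref_lifetime <= 0 or ref_qy <= 0:
        raise InvalidParameterError("reference lifetime and quantum yield must be > 0")
    tau_avg = amplitude_averaged_lifetime(components)
    return tau_avg, ref_qy * tau_avg / ref_lifetime
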