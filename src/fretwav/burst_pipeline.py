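"""Single-molecule burst selection, corrections and donor-only-free decays.

Bursts are detected on the PIE channel (acceptor emission under direct red
excitation): the inter-photon distance (IPD) trace is smoothed with a
centered moving average (width 7) and runs below a 50 us threshold mark
single-molecule transits.  Detecting on the PIE channel requires an active
acceptor, so donor-only molecules and acceptor-photobleached transits
never enter the selection.  Donor and acceptor photons falling inside a
detected burst interval (closed on both ends) are then background- and
crosstalk-corrected, burst-wise FRET efficiencies are computed as
``E = F_A / (F_A + gamma F_D)``, and the donor microtimes of all retained
bursts (total corrected intensity >= N_T) are binned into a donor decay
free of donor-only photons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import trim_mean

from .decay_model import TCSPCHistogram, TimeGrid
from .photon_sim import CHANNEL_ACCEPTOR, CHANNEL_DONOR, PhotonStream

__all__ = [
    "CorrectionFactors",
    "BurstSelection",
    "EfficiencyHistogram",
    "smooth_ipd",
    "detect_bursts",
    "estimate_background",
    "correct_burst_counts",
    "efficiency",
    "shot_noise_variance",
    "fit_efficiency_histogram",
    "process_bursts",
    "build_filtered_decay",
]


@dataclass
class CorrectionFactors:
    """Intensity correction constants of the burst analysis.

    ``gamma = gamma_prime * g`` combines the acceptor/donor quantum-yield
    ratio ``gamma_prime = phi_A/phi_D`` and the detection-efficiency ratio
    ``g = g_A/g_D``.  ``alpha`` is the donor cross-talk fraction into the
    acceptor channel.  Background rates are per-channel in counts/us
    (estimated from inter-burst stretches when not supplied).
    """

    gamma_prime: float = 0.36
    g: float = 1.3
    gamma: float | None = None
    alpha: float = 0.0085
    bg_donor_per_us: float = 0.0
    bg_acceptor_per_us: float = 0.0

    def __post_init__(self) -> None:
        product = self.gamma_prime * self.g
        if self.gamma is None:
            self.gamma = product
        elif abs(self.gamma - product) > 1e-6:
            raise ValueError(
                f"gamma={self.gamma} inconsistent with gamma_prime*g={product}"
            )
        if min(self.gamma_prime, self.g, self.gamma) <= 0 or self.alpha < 0:
            raise ValueError("correction factors must be positive")


def smooth_ipd(ipd_trace, width: int = 7) -> np.ndarray:
    """Centered moving average of an inter-photon-distance trace.

    ``width`` must be odd; near the edges the available (shorter) centered
    window is used.
    """
    if width % 2 == 0 or width < 1:
        raise ValueError("moving-average width must be odd and >= 1")
    x = np.asarray(ipd_trace, dtype=float)
    if width == 1 or x.size == 0:
        return x.copy()
    half = width // 2
    csum = np.cumsum(np.concatenate([[0.0], x]))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, x.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


@dataclass
class BurstSelection:
    """Detected burst intervals plus per-burst photon bookkeeping."""

    table: pd.DataFrame
    donor_microtimes: list = field(default_factory=list)


def detect_bursts(
    pie_macrotimes_us, threshold_us: float = 50.0, width: int = 7
) -> pd.DataFrame:
    """Burst intervals from the PIE-channel inter-photon-distance trace.

    Returns a table with columns ``start_us``, ``end_us`` and
    ``n_pie`` (photons of the run).  Fewer than two PIE photons yield an
    empty table.
    """
    t = np.asarray(pie_macrotimes_us, dtype=float)
    cols = {"start_us": [], "end_us": [], "n_pie": []}
    if t.size >= 2:
        smoothed = smooth_ipd(np.diff(t), width=width)
        below = smoothed < threshold_us
        # runs of consecutive below-threshold IPDs; IPD i joins photons i, i+1
        edges = np.diff(below.astype(int))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if below.size and below[0]:
            starts = np.concatenate([[0], starts])
        if below.size and below[-1]:
            ends = np.concatenate([ends, [below.size]])
        for i, j in zip(starts, ends):
            cols["start_us"].append(t[i])
            cols["end_us"].append(t[j])
            cols["n_pie"].append(j - i + 1)
    return pd.DataFrame(cols)


def estimate_background(
    stream: PhotonStream, bursts: pd.DataFrame, min_gap_us: float = 2000.0,
    trim: float = 0.1,
) -> tuple[float, float]:
    """Per-channel background rates (counts/us) from inter-burst stretches.

    Gap segments longer than ``min_gap_us`` between detected bursts are
    rated individually and combined with a trimmed mean, which is robust
    against undetected dim transits inflating single gaps.
    """
    t = stream.macrotime_us
    total_span = (t[0], t[-1]) if len(stream) else (0.0, 0.0)
    bounds = [total_span[0]]
    for _, row in bursts.iterrows():
        bounds += [row.start_us, row.end_us]
    bounds.append(total_span[1])
    rates_d, rates_a = [], []
    for lo, hi in zip(bounds[0::2], bounds[1::2]):
        if hi - lo < min_gap_us:
            continue
        sel = (t >= lo) & (t <= hi)
        dur = hi - lo
        rates_d.append(np.sum(stream.channel[sel] == CHANNEL_DONOR) / dur)
        rates_a.append(np.sum(stream.channel[sel] == CHANNEL_ACCEPTOR) / dur)
    if not rates_d:
        return 0.0, 0.0
    return (
        float(trim_mean(rates_d, trim)) if len(rates_d) > 2 else float(np.mean(rates_d)),
        float(trim_mean(rates_a, trim)) if len(rates_a) > 2 else float(np.mean(rates_a)),
    )


def correct_burst_counts(
    S_D: float, S_A: float, duration_us: float, cf: CorrectionFactors
) -> tuple[float, float]:
    """Background- and crosstalk-corrected burst intensities.

    ``F_D = S_D - BG_D * dur``; ``F_A = S_A - BG_A * dur - alpha * F_D``.
    Negative results are retained (flagged downstream), not clipped.
    """
    if S_D < 0 or S_A < 0:
        raise ValueError("raw counts must be non-negative")
    F_D = S_D - cf.bg_donor_per_us * duration_us
    F_A = S_A - cf.bg_acceptor_per_us * duration_us - cf.alpha * F_D
    return F_D, F_A


def efficiency(F_D: float, F_A: float, gamma: float = 0.47) -> float:
    """Burst-wise FRET efficiency ``E = F_A / (F_A + gamma F_D)``."""
    denom = F_A + gamma * F_D
    if denom == 0:
        raise ZeroDivisionError("efficiency undefined for F_A + gamma F_D = 0")
    return F_A / denom


def shot_noise_variance(mean_E: float, n_threshold: int) -> float:
    """Shot-noise-limited variance ``<E>(1 - <E>) / N_T`` of an efficiency peak."""
    if n_threshold < 1:
        raise ValueError("N_T must be >= 1")
    return mean_E * (1.0 - mean_E) / n_threshold


@dataclass
class EfficiencyHistogram:
    """Burst efficiency histogram with its fitted Gaussian population."""

    efficiencies: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    mean_E: float
    variance: float
    amplitude: float
    shot_noise_var: float
    n_threshold: int
    shot_noise_limited: bool


def fit_efficiency_histogram(
    efficiencies,
    n_threshold: int = 40,
    shot_noise_limited: bool = True,
    n_bins: int = 41,
) -> EfficiencyHistogram:
    """Gaussian fit of a burst-efficiency histogram.

    With ``shot_noise_limited`` the Gaussian variance is pinned to
    ``<E>(1-<E>)/N_T`` (only mean and amplitude are free), the expected
    width when all broadening beyond photon counting statistics has been
    averaged out by fast distance fluctuations.
    """
    e = np.asarray(efficiencies, dtype=float)
    if e.size < 30:
        raise ValueError("need at least 30 bursts to fit an efficiency histogram")
    counts, edges = np.histogram(e, bins=n_bins, range=(-0.1, 1.1))
    centers = 0.5 * (edges[1:] + edges[:-1])
    mu0 = float(np.clip(np.mean(e), 0.01, 0.99))
    a0 = float(counts.max())
    if shot_noise_limited:

        def model(x, a, mu):
            var = shot_noise_variance(np.clip(mu, 1e-3, 1 - 1e-3), n_threshold)
            return a * np.exp(-0.5 * (x - mu) ** 2 / var)

        popt, _ = curve_fit(model, centers, counts, p0=[a0, mu0])
        amp, mu = popt
        var = shot_noise_variance(float(np.clip(mu, 1e-3, 1 - 1e-3)), n_threshold)
    else:

        def model(x, a, mu, sig):
            return a * np.exp(-0.5 * (x - mu) ** 2 / sig**2)

        popt, _ = curve_fit(model, centers, counts, p0=[a0, mu0, max(np.std(e), 0.01)])
        amp, mu, sig = popt
        var = float(sig**2)
    return EfficiencyHistogram(
        efficiencies=e,
        bin_edges=edges,
        counts=counts,
        mean_E=float(mu),
        variance=float(var),
        amplitude=float(amp),
        shot_noise_var=shot_noise_variance(float(np.clip(mu, 0.0, 1.0)), n_threshold),
        n_threshold=n_threshold,
        shot_noise_limited=shot_noise_limited,
    )


def process_bursts(
    stream: PhotonStream,
    cf: CorrectionFactors | None = None,
    threshold_us: float = 50.0,
    width: int = 7,
    n_threshold: int = 40,
    red_start_ns: float = 25.0,
) -> BurstSelection:
    """Full burst pipeline: detect on the PIE channel, correct, select.

    Returns a burst table (raw counts ``S_D``/``S_A`` in the green window,
    PIE-window count, corrected ``F_D``/``F_A``, efficiency, selection
    flag ``selected`` for ``F_D + F_A >= N_T``) plus the donor green-window
    microtimes of every burst for decay building.  Background rates are
    estimated from inter-burst stretches unless provided in ``cf``.
    """
    cf = cf or CorrectionFactors()
    green = stream.microtime_ns < red_start_ns
    is_pie = (stream.channel == CHANNEL_ACCEPTOR) & ~green
    bursts = detect_bursts(stream.macrotime_us[is_pie], threshold_us, width)
    if cf.bg_donor_per_us == 0.0 and cf.bg_acceptor_per_us == 0.0 and len(bursts):
        bg_d, bg_a = estimate_background(stream, bursts)
        # split channel totals: donor background is all green; acceptor
        # background spreads over the full cycle, half of it in the green window
        cf.bg_donor_per_us = bg_d
        cf.bg_acceptor_per_us = bg_a * (red_start_ns / 50.0)
    t = stream.macrotime_us
    donor_green = (stream.channel == CHANNEL_DONOR) & green
    acc_green = (stream.channel == CHANNEL_ACCEPTOR) & green
    td, ta, tp = t[donor_green], t[acc_green], t[is_pie]
    micro_d = stream.microtime_ns[donor_green]
    rows, micro_per_burst = [], []
    for _, row in bursts.iterrows():
        lo, hi = row.start_us, row.end_us
        # closed interval membership on both ends
        d_sel = slice(np.searchsorted(td, lo, "left"), np.searchsorted(td, hi, "right"))
        a_sel = slice(np.searchsorted(ta, lo, "left"), np.searchsorted(ta, hi, "right"))
        p_sel = slice(np.searchsorted(tp, lo, "left"), np.searchsorted(tp, hi, "right"))
        S_D = d_sel.stop - d_sel.start
        S_A = a_sel.stop - a_sel.start
        dur = hi - lo
        F_D, F_A = correct_burst_counts(S_D, S_A, dur, cf)
        try:
            E = efficiency(F_D, F_A, cf.gamma)
        except ZeroDivisionError:
            E = np.nan
        rows.append(
            {
                "start_us": lo,
                "end_us": hi,
                "duration_us": dur,
                "S_D": S_D,
                "S_A": S_A,
                "n_pie": p_sel.stop - p_sel.start,
                "F_D": F_D,
                "F_A": F_A,
                "E": E,
                "selected": bool(np.isfinite(E) and (F_D + F_A) >= n_threshold),
            }
        )
        micro_per_burst.append(micro_d[d_sel])
    table = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["start_us", "end_us", "duration_us", "S_D", "S_A", "n_pie",
                 "F_D", "F_A", "E", "selected"]
    )
    return BurstSelection(table=table, donor_microtimes=micro_per_burst)


def build_filtered_decay(
    selection: BurstSelection,
    bin_width_ns: float = 0.016,
    span_ns: float = 25.0,
    selected_only: bool = True,
) -> TCSPCHistogram:
    """Donor decay histogram from the microtimes of retained bursts.

    Because bursts were detected on the PIE channel, the histogram contains
    no donor-only photons.  ``selected_only=False`` bins all detected
    bursts regardless of the intensity threshold (useful for comparison).
    """
    if not len(selection.table):
        raise ValueError("no bursts to build a decay from")
    mask = selection.table["selected"].to_numpy() if selected_only else np.ones(
        len(selection.table), dtype=bool
    )
    if not mask.any():
        raise ValueError("no bursts passed the selection criteria")
    micro = np.concatenate(
        [m for m, keep in zip(selection.donor_microtimes, mask) if keep]
        or [np.empty(0)]
    )
    if micro.size == 0:
        raise ValueError("selected bursts contain no donor photons")
    n_bins = int(round(span_ns / bin_width_ns))
    counts, _ = np.histogram(micro, bins=n_bins, range=(0.0, n_bins * bin_width_ns))
    grid = TimeGrid(bin_width=bin_width_ns, n_bins=n_bins)
    return TCSPCHistogram(grid=grid, counts=counts.astype(float))
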