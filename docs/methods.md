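# Methods

This note documents the models implemented in `fretwav`, the choices made
where the underlying procedures are genuinely open, and what the synthetic
data used in the tests do and do not establish about real measurements.

## Donor decay model

A FRET donor with local quenching is described by a multi-exponential
donor-only decay with amplitude fractions `x_i` and lifetimes `tau_i`
(`sum x_i = 1`).  In the presence of an acceptor at distance `R`, each
component's decay rate is multiplied by `1 + (R0/R)^6`, where `R0` is the
Förster radius; the transfer efficiency is `E = 1/(1 + (R/R0)^6)`.  Fast
dye-linker diffusion (≈100 ns) relative to the donor lifetime motivates a
quasi-static distance distribution `p(R)`, well approximated by a Gaussian
with mean `<R_DA>` and standard deviation `sigma_DA`; the FRET-quenched
decay is the `p(R)`-weighted average of the quenched exponentials.  The
total model adds a donor-only molecule fraction `x_D0` (same lifetime
components, no quenching), a peak amplitude `I0` and a constant background
`BG` per bin, and is convolved with the instrument response function (IRF)
when one is supplied.

Numerical choices:

* Curves are evaluated at bin centers; at 16 ps bins versus nanosecond
  lifetimes, bin-center evaluation and bin integration are
  indistinguishable.
* The Gaussian is discretized over `<R> ± 4 sigma` with a 0.25 Å step
  (refined automatically when `sigma` is so small that fewer than ~25
  points would fall in the interval) and the truncated weights are
  renormalized to unit mass, so `x_D0` keeps its exact interpretation as a
  molecule fraction.  A switch restores the raw truncated mass (the
  difference is ~6e-5).
* The lower integration bound is clipped at 1 Å to keep `(R0/R)^6`
  finite.
* Periodic-wrap reconvolution is available but off by default: with a
  50 ns period and a fit window ending at 40 ns, wrap effects are
  negligible for nanosecond lifetimes.

## Fitting and error analysis

Fits minimize the Poisson deviance (maximum likelihood, expressed as a
least-squares problem on signed deviance residuals) with a bounded
trust-region minimizer, convergence at a relative cost decrease of 1e-10.
The reported goodness of fit is the conventional Neyman-weighted reduced
chi-square `sum (d-m)^2/max(d,1) / nu`.

Why not minimize that statistic directly?  Weighting residuals by the
*observed* counts systematically favors downward fluctuations in
low-count bins.  The donor-only amplitude lives in the low-count tail, and
at the few-percent `x_D0` this analysis targets, the Neyman minimum is
visibly biased: on synthetic decays (mean 60 Å, `x_D0 = 0.05`,
`I0 = 1e4`) it pushes `x_D0` to ~0 and inflates both `sigma_DA` (+0.8 Å)
and `<R_DA>` (+0.9 Å) on every noise realization; Pearson (model)
weighting biases the opposite way.  The deviance estimator shows no bias
at the same conditions (replicate means 60.04 ± 0.08 Å) while behaving
identically to chi-square weighting for well-populated bins.  The Neyman
statistic is still the right *report*: its expectation exceeds 1 by
~`2/counts` per bin, which reproduces the characteristic values near
1.03–1.06 for these decays (larger for the faster-decaying high-FRET
state, whose window contains more near-background bins).

The fit window runs from 1 ns before the measured peak (located on the
data) to 40 ns.  The IRF is area-normalized before reconvolution; a
constant IRF offset can be subtracted using pre-peak bins.

Uncertainties use the F-statistic on the minimized surface.  The joint
confidence region at probability `1-P` is bounded by the statistic ratio
`F_chi = 1 + (k/nu) F(k, nu; 1-P)` with `k` free parameters and `nu`
degrees of freedom (`P = 0.32` for one standard deviation).  Confidence
surfaces are evaluated on a 3-D grid over `(sigma_DA, <R_DA>, x_D0)` with
`I0`, `BG` fixed at the minimum.  Per-parameter support-plane intervals
scan one parameter away from its estimate, re-minimize all other free
parameters at every scan point (warm-started), and bracket-and-bisect the
threshold crossing; when a parameter reaches a hard bound (e.g.
`x_D0 = 0`) before crossing, the bound is reported as a one-sided limit.

## Artificial-decay study

The donor-only bias study generates Poisson-noise decays from the total
model at `I0 = 1e4`, `BG = 20`, `sigma_DA = 6 Å`, means of 40 Å
(high FRET) and 60 Å (low FRET), and donor-only fractions 0–50%, on 3125
bins of 16 ps (50 ns).  No IRF is applied (a delta response), so the model
is fitted directly.  Donor components and Förster radii follow the
single-labeled reference constructs per FRET state: `x = (0.94, 0.06)`,
`tau = (4.06, 1.38) ns`, `R0 = 53.1 Å` for the high-FRET state and
`x = (0.91, 0.09)`, `tau = (4.09, 1.52) ns`, `R0 = 53.6 Å` for the
low-FRET state.  Start guesses simulate ignorance of the truth (mean
35/53 Å, width 8 Å, `0.9 x_D0`); `I0` and `BG` are fixed at truth.
Precision is the support-plane relative error `delta_xi / xi`; accuracy is
the signed relative deviation `(xi - xi_true)/xi_true`.

One replicate per condition is the default; the acceptance checks use 10
independent noise seeds per condition for stable statistics.  Two
estimator facts surfaced by replication are worth recording.  First, when
the true `x_D0` is 0, the free estimate sits at its bound and can only
drift upward, which induces a small (~0.1 Å) one-sided bias in the
fitted mean; recovery tests therefore fix `x_D0` at its true zero.
Second, the mean-distance accuracy bound of 0.5% at `x_D0 = 0.05` equals
roughly one standard deviation of the estimator noise implied by its own
precision (~0.75% support-plane half-width), so across seeds the bound
holds with probability ~0.8 per realization — a single-realization study
cannot distinguish this from "always holds", and an 8-of-10-seeds
criterion on it is marginal by construction.

## Photon-stream simulator and burst pipeline

The simulator emulates a pulsed-interleaved-excitation (PIE) confocal
measurement at 20 MHz: a 50 ns cycle with the donor pulse at 0 ns and the
direct-acceptor pulse at 25 ns; each photon carries a macrotime (µs), a
microtime (ns) and an emission channel.  Molecule transits are rectangular
rate episodes (log-normal durations, median 1 ms) over Poisson background
— enough structure to exercise inter-photon-distance burst selection;
diffusion, triplet kinetics and photobleaching are deliberately absent,
and acceptor blinking is represented only through the donor-only fraction
knob.  Default rates give ~75 detected green-window photons per transit,
comparable to threshold-passing single-molecule bursts.

Per green excitation the sampler draws a distance from the Gaussian
(fast-exchange: redrawn every photon), a lifetime component `i ~ x_i`, and
branches acceptor emission with probability `E(R)`.  Donor photons get
microtimes from `Exp(tau_i (1-E))`; FRET-sensitized acceptor photons add
the acceptor lifetime in cascade; Gaussian IRF jitter and an offset are
applied.  Emission probabilities carry the component's relative quantum
yield (`∝ tau_i`): without this factor short-lifetime components are
over-represented among photons relative to the amplitude fractions of the
decay model, which measurably biases downstream fits.  With it, the donor
microtime histogram follows the fitted model exactly in expectation, and
burst-wise efficiencies corrected with `gamma = gamma' g` are unbiased.

The pipeline smooths the PIE-channel inter-photon-distance trace with a
centered 7-point moving average, marks runs below 50 µs as bursts
(boundaries at the first/last PIE photon of the run; membership of other
photons by closed interval), estimates background rates from inter-burst
stretches (trimmed mean over gaps > 2 ms), applies the background and
crosstalk corrections, computes burst-wise efficiencies
`E = F_A/(F_A + gamma F_D)`, and retains bursts with `F_D + F_A >= 40`.
Donor-only molecules never trigger the PIE channel, so the decay built
from retained-burst donor microtimes is free of donor-only photons.  The
moving-average filter trims a few photons at burst edges and occasionally
splits long bursts; this costs photons uniformly in microtime and leaves
the decay shape unaffected.  Efficiency histograms can be fitted
shot-noise-limited, pinning the Gaussian variance to `<E>(1-<E>)/N_T`
with the count threshold `N_T = 40`.

Identifiability caveat: `sigma_DA` and `x_D0` separate only with good
counting statistics.  Below roughly 10^3 counts at the decay peak a
degenerate solution (`sigma -> 0`, residual `x_D0` absorbing the tail) can
be the likelihood optimum; the examples therefore accumulate photons until
the peak is well into the thousands, matching the >10^4-peak-counts
practice for filtered decays.

## Idealized B-DNA and the (weighted) accessible volume

Each nucleotide is reduced to three pseudo-atoms on a canonical B-form
helix (rise 3.4 Å, twist 36°): phosphate (radius 2.9 Å at helix radius
9.4 Å), sugar (2.9 Å at 7.4 Å) and base (3.5 Å at 2.5 Å), with backbone
and base azimuths offset ±77°/±55°/±33° from the base-pair pseudo-dyad for
the two antiparallel strands.  This reproduces the ~2 nm steric envelope
that the accessible-volume calculation is sensitive to; sequence-dependent
fine structure, bending and mismatch distortion are not modeled (the
10-bp construct's mismatch is built as standard geometry).  The dye
attachment point is the labeled base pseudo-atom displaced 3 Å radially
outward.

The accessible volume (AV) of a dye is the set of grid cells (0.8 Å
default spacing, 0.4 Å alternative) that (i) are reachable from the
attachment through free space within the linker contour length `L_link`,
(ii) clear the linker tube of width `w_link` (cell center farther than
`atom radius + w_link/2` from every obstacle atom), and (iii) clear the
dye, coarse-grained as an ellipsoid with semiaxes `R_dye,1..3` treated as
the union of three sphere-radius tests (free rotation justifies
orientation-averaging).  Dye-linker dimensions for the two constructs:
donor T-C6-Alexa 488 `L=19.3, w=4.5, R=(5.2, 4.2, 1.5) Å`; acceptor
T-C6-Alexa 647 `L=24.6, w=4.5, R=(9.9, 7.7, 1.5) Å`.

Path lengths: where the straight segment from the attachment point is
unobstructed, the path length is the exact Euclidean distance; shadowed
cells are completed by a label-correcting shortest path over an extended
124-offset stencil (all nonzero integer offsets within Chebyshev radius
2, with intermediate-cell checks so paths cannot tunnel through walls),
seeded from the line-of-sight distances.  A pure grid metric was rejected
on accuracy grounds: the common 26-neighbor stencil overestimates
Euclidean lengths by up to ~8% depending on direction, which shrinks a
free-space reachability ball by ~22% in volume at any spacing; the hybrid
is exact in open space and errs slightly conservatively (over-long paths,
hence exclusion) only behind obstacles.  A corollary is that results here
are nearly grid-independent: refining 0.8 → 0.4 Å moves the mean and the
width of the inter-dye distance distribution by well under 1%.
Implementations whose path metric or boundary handling is
resolution-dependent can show width changes of order 10% between these
spacings; this package does not reproduce that sensitivity.

Near the attachment, the three-site model places the labeled base's own
sugar and neighboring bases within the linker-tube clash distance of the
attachment point.  The labeled base pseudo-atom is excluded from the
obstacle set (standard practice for the attachment atom), and cells within
`w_link` of the attachment are exempt from the linker-width block — the
covalently bonded first linker segment necessarily occupies that shell.
Dye-size clearance remains strict everywhere.  An attachment is rejected
as buried when no genuinely free cell exists near the exemption shell.

The plain AV weights points uniformly.  The weighted AV (wAV) multiplies
each point by a Gaussian occupancy `exp(-|R - R_attach|^2 / (2 sigma_AV^2))`,
normalized over the discrete cloud, with the width from an ideal-chain
model of the linker: `sigma_AV = sqrt(b_eff L_link / 3)` (one Cartesian
component of a chain with mean-square end-to-end distance `b_eff L_link`);
an alternative rigid-linker scaling `b_eff sqrt(L_link/3)` is selectable.
`sigma_AV` is applied per dye with its own `L_link`.  The effective bond
length `b_eff` is calibrated by root-finding the value whose wAV width
matches a measured `sigma_DA` on an intrinsically rigid standard.

Inter-dye statistics (mean and standard deviation of `|R_D - R_A|` over
all weighted point pairs) are exact for up to 6·10^8 pairs (blocked double
sum); beyond that the mean uses seeded weight-proportional pair sampling
(2·10^6 pairs by default, standard error ~0.01 Å) while the second moment
is always exact through single-cloud moments, so the width inherits only
the mean's small sampling error.

## What the synthetic data do not show

The decay study establishes estimator properties (bias, precision,
chi-square behavior) under exactly the generating model; real decays add
IRF uncertainty, pile-up, scattered light and detector afterpulsing.  The
photon-stream simulator validates the pipeline's bookkeeping and the
donor-only filtering logic, not diffusion-driven burst-size distributions
or photophysical artifacts.  The idealized B-DNA stand-in reproduces the
duplex envelope, not an all-atom surface: predicted AV means carry an
uncertainty of a couple of Ångström from the structure model alone, and
the AV widths of the smooth three-site surface are a few percent narrower
than those of a corrugated all-atom structure.  Within those limits, the
wAV calibration (optimal `b_eff ≈ 3.6 Å` against a 7.2 Å measured width)
and the AV/wAV distance statistics are reproduced on the stand-in.

## Problem sizes used by the tests and acceptance script

Replicated study: 7 donor-only fractions × 2 means × 10 seeds (140 fits);
tolerance study at `x_D0 = 0.05`: 2 means × 10 seeds with support-plane
intervals for the mean and width; AV clouds: ~1.2·10^4 / 3.7·10^4 points
(0.8 Å) and ~1.0·10^5 / 3.1·10^5 points (0.4 Å) for donor/acceptor;
end-to-end stream: 400 s at 12 bursts/s with 50% donor-only molecules.
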