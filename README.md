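# fretwav

Inter-dye distance distributions from FRET-filtered fluorescence-lifetime
data, with a weighted accessible-volume (wAV) model of the dye linkers.

## The problem

Time-resolved FRET measures the donor fluorescence decay of a
donor–acceptor pair and infers the distribution of inter-dye distances
`p(R_DA)` — mean `<R_DA>` and width `sigma_DA` — with Ångström-scale
resolution.  Two effects corrupt this in practice:

1. **Donor-only molecules.**  A fraction `x_D0` of molecules lacks an
   active acceptor.  Their unquenched decay is strongly anti-correlated
   with `sigma_DA` and `<R_DA>` in the fit, degrading both precision and
   accuracy unless `x_D0` is pushed below a few percent.  Single-molecule
   measurements with pulsed interleaved excitation (PIE) can remove this
   population photon-by-photon: bursts are detected on the directly
   excited acceptor (PIE) channel, which donor-only molecules never
   trigger, and the lifetime decay is built only from retained bursts.
2. **Dye linkers.**  The ~20 Å flexible linkers let the dyes diffuse over
   an accessible volume (AV), shifting mean positions and adding width.
   The AV algorithm predicts `<R_DA>` well but overestimates `sigma_DA`
   because it occupies all sterically allowed positions uniformly.  The
   wAV variant weights each AV point by a Gaussian occupancy centered at
   the attachment point, with width `sigma_AV = sqrt(b_eff L_link / 3)`
   from an ideal-chain model of the linker; the effective bond length
   `b_eff` is calibrated once on an intrinsically rigid standard
   (double-stranded DNA) and then ports to other constructs with the same
   dyes.

`fretwav` implements the full workflow: TCSPC decay models and
reconvolution fitting with support-plane error analysis, artificial-decay
studies of the donor-only bias, a synthetic PIE photon-stream simulator
with the burst-filtering pipeline, an idealized B-DNA builder for the
labeled duplexes, and the AV/wAV distance-distribution calculation.

## The model in brief

Donor decay with local quenching: `F_D0(t) = I0 sum_i x_i exp(-t/tau_i)`.
FRET quenches each component at distance `R` by the rate factor
`1 + (R0/R)^6` (efficiency `E = 1/(1 + (R/R0)^6)`), averaged over a
Gaussian `p(R_DA)`:

    F_DA(t) = sum_i x_i ∫ p(R) exp[-(t/tau_i)(1 + (R0/R)^6)] dR
    F(t)    = I0 [(1 - x_D0) F_DA(t) + x_D0 F_D0(t)] + BG
    I(t)    = IRF(t) * F(t)

Fits are Poisson maximum likelihood; goodness of fit is the reduced
chi-square; confidence surfaces and per-parameter support-plane intervals
use the F-statistic threshold `1 + (k/nu) F(k, nu; 1-P)`.  Burst
efficiencies are `E = F_A/(F_A + gamma F_D)` after background and
crosstalk corrections (`gamma = gamma' g`, defaults 0.36 × 1.3 ≈ 0.47,
`alpha = 0.85%`), and shot-noise-limited histogram peaks have variance
`<E>(1-<E>)/N_T` with `N_T = 40`.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

`examples/` contains one short script per capability.  For instance,
recovering a clean distance distribution from a stream in which **half**
of the molecules are donor-only (`python examples/03_burst_filtered_lifetime.py`):

    3614147 photons in 900 s of simulated measurement
    12572 bursts detected on the PIE channel, 7468 retained
    <E> = 0.357, shot-noise-limited sigma = 0.076
    filtered-decay fit: <R_DA> = 60.0 A, sigma_DA = 6.5 A, x_D0 = 0.014 (stream truth: 50% donor-only molecules)

The stream was generated with `<R_DA> = 60 Å`, `sigma_DA = 6 Å`: burst
detection on the PIE channel removed the donor-only population (fitted
`x_D0` 1.4% instead of 50%), the mean efficiency matches the
photon-averaged truth, and the decay fit recovers the distance
distribution.  And the structure side
(`python examples/04_wav_distance_prediction.py`):

    plain AV:   <R_DA> = 65.0 A, sigma_DA = 10.0 A
    wAV (b_eff=3.6 A): <R_DA> = 60.1 A, sigma_DA = 7.1 A

— Gaussian occupancy weighting barely moves the predicted mean but
shrinks the predicted width toward what filtered lifetime measurements on
rigid DNA show.

A thin command line mirrors the library
(`fretwav simulate-decay | fit-decay | study | simulate-stream | bursts |
filtered-fit | build-dna | wav | calibrate`); every subcommand writes a manifest with the
effective configuration, seed and output checksums.

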