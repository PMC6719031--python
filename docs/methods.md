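# Methods

## The measurement being modelled

Whole-cell currents through heat-activated channels are recorded at a
holding potential of −70 mV while the bath is heated by ramp-shaped stimuli
from ~25 °C to a per-sweep peak (50–60 °C) within 1500 ms, repeated at 3 s
intervals. The analysis chain characterises each sweep's rising phase by an
Arrhenius plot — ln of the absolute current against reciprocal absolute
temperature after pooling samples per 0.25 °C — and summarises it by the
maximal apparent temperature coefficient Q10, the temperature range over
which the plot is acceptably straight, and a fixed-range low-temperature
Q10. These apparent quantities conflate gating thermodynamics, kinetics and
stimulus speed; they are operational descriptors, not equilibrium
enthalpies, which is exactly why the pipeline fixes every convention
(binning pitch, r² rule, tie-breaks) explicitly.

## Ramp waveform

`RampProtocol` describes a train of identical sweeps with period
`inter_sweep_s` (default 3 s): a rise of `rise_ms` (default 1500 ms)
followed by exponential re-cooling to the base temperature (time constant
one tenth of the cooling interval, so the residual at the next sweep start
is below 0.01 °C). Two rise shapes are provided:

- `linear` — constant slope `(T_peak − T_base)/rise`;
- `exp_approach` (default) — `T(t) = T_base + A(1 − e^(−kt))` with the
  asymptote excess `A` solved (Brent's method) so that the **maximal slope
  equals the configured `max_speed`** (default 35 °C/s, the measured maximal
  heating rate of fast perfusion systems) *and* the peak is reached exactly
  at `rise_ms`. A linear 1500-ms ramp to 57 °C could only reach ~21 °C/s,
  so the published maximal speed forces a decelerating profile.

The generated waveform's maximal discrete slope matches the configured
speed to <1 % at the default 1 kHz sampling.

## Channel model

The simulated current is

    I(t) = N_g_max · q10_g^((T−25)/10) · Po_eff(T, s) · (vhold − Vrev)
         + leak_g · q10_leak^((T−25)/10) · (vhold − leak_Vrev)
         + sub_g · Po_sub(T) · (vhold − leak_Vrev)
         + ε,    ε ~ N(0, noise_sd²)

with conductances in nS, potentials in mV, currents in pA (inward negative
at −70 mV; the analysis uses |I|).

**Gating.** The pore is a quasi-equilibrium two-state gate with van't Hoff
open probability `Po(T) = 1/(1 + exp((ΔH − TΔS − ΔG_agonist)/(RT)))`. Use
dependence — the irreversible sensitization of the channel by
supra-threshold heat — is modelled as a second, "sensitized" gating mode
with lower enthalpy and lower midpoint; the sensitized fraction obeys

    ds/dt = sens_rate · max(0, T − sens_T) · (1 − s),

integrated exactly along the temperature trajectory, so `s` is
non-decreasing (never resets between sweeps) and `Po_eff = (1−s)·Po_naive +
s·Po_sens`. This equilibrium-plus-mode-switch formalism is an explicit
stand-in: the true gating kinetics of strongly use-dependent heat-gated
channels are unknown and irreversibility precludes a simple equilibrium
description. The stand-in was chosen because it reproduces, with one
mechanism, every observable the analysis consumes: a steep initial limb
whose apparent Q10 depends on ramp speed, the drop of Q10 once the
sensitized mode dominates, and thresholds that emerge from the crossover of
channel current over background. A generalized drive with an exponential
(Arrhenius-like) temperature dependence is available through
`sens_softness`; the presets use the linear drive, which proved sufficient.

**Background.** Two components: an ohmic leak with conductance Q10 ≈ 1.3,
and a small *saturating* sub-threshold pathway — a low-enthalpy gate
(`sub_dH` ≈ 90 kJ/mol, midpoint ≈ 48 °C). Their mixture yields a background
whose apparent Q10 is ~1.8 over 26–34 °C while the tail of the steep naive
gate raises the apparent Q10 just below threshold to ~2.8 (45–48 °C). A
single power-law leak cannot do this: its Arrhenius slope is
temperature-independent, and during calibration no single-Q10 background
could satisfy both the low-range and the sub-threshold values at once.

**Why the steep limb cannot be purely equilibrium.** An instructive
constraint found during model design: a two-state gate with apparent
Q10 ≈ 22 grows only ~3× between 48 and 52 °C, so it cannot be negligible at
48 °C (sub-threshold Q10 2.8) *and* dominate the current at 51.7 °C
(threshold). In the model the initial-response steepness is therefore partly
dynamic — the sensitized fraction rising during the ramp — which is also
what makes the apparent Q10 co-vary with ramp speed across cells, as
observed experimentally.

## Presets and calibration

`wild_type` (also `dtt_rescued`): ΔH = 355 kJ/mol, midpoint 58.5 °C;
sensitized mode ΔH = 248 kJ/mol, midpoint 56.5 °C; N·g = 19 nS; leak
0.35 nS (Q10 1.3); sub-threshold gate 2.42 nS, ΔH 90 kJ/mol, midpoint
48 °C; sens_T 49.3 °C, sens_rate 0.45 s⁻¹K⁻¹; noise 20 pA SD. The
thermodynamic parameters and the sensitization rate were calibrated by
forward simulation so that the packaged pipeline run on seed-fixed cohorts
reproduces the published wild-type statistics (initial median maximal Q10 in
the low twenties over ~51.7–53.9 °C, second-response median ~10.6, low-range
Q10 1.8, sub-threshold Q10 2.8, 35 °C/s maximal ramp speed); the rate
constant is calibrated, not measured.

Per-cell variability (log-normal on enthalpies, gains and sensitization
rate; normal on mode midpoints and on maximal ramp speed, SD 2 °C/s) is
sized to reproduce the published magnitude of cell-to-cell spread of Q10
and threshold. Other presets alter only what the phenotype requires:
`sensitized_chimera` starts fully sensitized (s₀ = 1) with a low-midpoint
sensitized mode (tonic activity at 25 °C), `heat_resistant` shifts both
midpoints up ~12 °C with reduced expression, `locked_open` forces
Po ≡ 1 (near-linear current–temperature relationship).

Problem sizes used by the packaged reproduction script — 25 cells (initial
responses), 14 paired cells, 9 sub-threshold cells at 1 kHz sampling —
mirror the published cohort sizes and keep a full run in seconds.

## Analysis conventions

- **Binning:** half-open `[T, T+0.25)` anchored at 0 °C; per-bin mean of
  |I|; partial edge bins are kept; < 8 occupied bins is an error.
- **Rising phase:** temperature smoothed by a centered 5-ms moving average;
  onset is the start of the last contiguous run with dT/dt > 1 °C/s before
  the raw temperature peak. The onset rule is our stated convention; the
  published procedure does not define one.
- **Segment search:** exhaustive over all contiguous windows of ≥ 8 bins
  (≥ 2 °C), maximizing |slope| subject to r² ≥ 0.98. Ties (within a 1e−9
  relative slope tolerance, so exactly collinear data behaves sensibly) go
  to the wider window, then to the higher lower limit. A brute-force
  per-window regression is kept in the test suite as an independent oracle.
  Raising `r2_min` can only shrink the qualifying set, so the attained
  maximal |slope| is non-increasing in `r2_min`; the *width* of the
  returned window is not monotone in general (a narrow noisy window can
  qualify only at low `r2_min`), which is why the monotonicity test checks
  the slope, not the width.
- **Threshold:** the lower temperature limit of the maximal-Q10 segment.
- **Q10:** `exp(10·Ea/(R·T1·T2))`, `Ea = −slope·R`, R = 8.314 J/(mol·K).
- **Normalization:** subtract the 26.0–26.25 °C bin mean of the same sweep,
  divide by the maximum of the subtracted curve, clip at 0. Grid points a
  cell never visited are masked (NaN), not zero-filled; SEM is the n−1
  standard deviation over contributing cells divided by √n.
- **Cohort tests:** Student's t (paired/independent) on log Q10 — the
  natural scale for a ratio-type coefficient; a zero-difference paired
  comparison reports p = 1 by convention. One-way ANOVA with Dunnett's post
  hoc versus a control group via scipy. Medians and quartiles are reported
  alongside, as is customary for skewed Q10 distributions.

## Structural distances

`structure_distances` measures Cα–Cα distances between residue pairs across
*adjacent* subunits of a homotetramer from mmCIF (preferred) or PDB files
(gemmi; first model, first alt-loc). Because which cyclic neighbour carries
the partner residue is a labelling convention that deposited files do not
fix, `pair_report` evaluates every cyclic chain pairing in both directions
and reports the minimum (the designed contact is the shortest inter-subunit
realisation); `all_pairings=True` prints all of them. Residue numbers follow
the deposited mouse TRPV3 construct; note that functional work on human
TRPV3 uses human numbering, which is offset for some regions — when mapping
mutagenesis positions onto the mouse structures, verify the alignment around
the finger-3 loop (e.g. human H256/F259 correspond to the equivalently
numbered residues of the mouse construct in the deposited files).

## What the synthetic data does and does not show

The generator emulates the statistical structure the analysis relies on:
amplitudes, noise floor, binwise sampling density, use-dependent steepening
and the cell-to-cell spread of thresholds and Q10. It does not emulate
capacitive transients, 1/f noise, seal drift, desensitisation during the
cooling phase, stochastic single-channel gating, or agonist
concentration–response — so green tests demonstrate the *pipeline's*
correctness and the self-consistency of the calibrated model, not the
validity of the two-state + mode-switch stand-in as a mechanistic model of
any real channel.

## Numerical and degenerate-input choices

- Open probabilities are computed with `scipy.special.expit` (no overflow).
- The sensitization ODE uses the exact exponential-integrator update, so
  `s` is monotone and bounded for any step size.
- Loader/writer round-trip is bit-exact (shortest-repr floats on write,
  `float_precision="round_trip"` on read).
- Flat or cooling-only sweeps raise a "no ramp detected" error; constant
  currents raise a degenerate-curve error at normalization; bins with
  non-positive means are excluded from the Arrhenius transform.
- Windows of fewer than 8 bins (2 °C) are never fitted, preventing
  spuriously steep two-point segments.

## Known limitations

- The threshold estimate is convention-bound (lower limit of the steepest
  r²-qualifying window) and shifts by a few tenths of a °C with noise
  level, ramp speed and `min_bins`.
- Apparent Q10 values from ramp data are speed-dependent by construction;
  comparisons are only meaningful at matched protocols.
- The sensitized-mode thermodynamics are calibrated to cohort statistics,
  not identified from kinetics; different (ΔH_sens, sens_rate) pairs can
  produce nearly indistinguishable cohort summaries.
- `pair_report`'s minimum-over-pairings rule assumes the designed contact
  is the shortest realisation; for structures with large conformational
  asymmetry between chains, inspect `all_pairings=True` output.
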