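# Methods

## Model

The network is a mean-field (neural-mass) description of a patch of
macaque V1: 225 excitatory-inhibitory (E-I) units on a 15 x 15
lattice, each representing one or a few hypercolumns, plus a single
global excitatory node G standing in for higher visual cortex
(V2/V4).  Per-unit dynamics are leaky rate equations with half-wave
rectification H(x) = max(x, 0) applied inside every interaction term
("firing rates cannot be negative"), while the state variables
themselves may go negative; the local field potential (LFP) is the
*unrectified* E of the central unit, the conventional LFP proxy in
this model family.  Multiunit activity (MUA) is the analysis-window
mean of H(E) (and H(G)).

Connection classes and reference values (dimensionless couplings;
time constants in seconds):

| group | parameter | default | meaning |
|---|---|---|---|
| time constants | tau_E, tau_I, tau_G | 0.006, 0.012, 0.019 | E fastest, G slowest |
| feed-forward | W_EL, W_IL | 1.75, 1.25 | LGN -> E, LGN -> I |
| local recurrent | W_EE^RC, W_IE^RC | 1.5, 3.5 | E -> E, E -> I |
| local recurrent | W_EI^RC, W_II^RC | -3.25, -2.5 | I -> E, I -> I (sign in the weight) |
| horizontal | W_EE^HC, W_IE^HC | 0-0.03, 0-4.5 (swept) | E -> E, E -> I across units |
| horizontal | sigma | 4 (lattice units) | Gaussian kernel width |
| feedback | W_EG, W_IG | 0-0.27, 0-0.45 (swept) | G -> E, G -> I |
| feed-forward to G | W_GE | 0.1 | each E -> G |

Horizontal weights follow K(i,j) = W exp(-d_ij^2 / 2 sigma^2) / sigma
with Euclidean distance on the integer lattice, no self-connection
(j != i) and open boundaries: the sheet is a piece of cortex, not a
torus, so edge units receive less total horizontal input.  Only E
projects horizontally (inhibition is local).

The stimulus ("grating of a given size") sets the mean LGN rate:
40 Hz for units within `radius` lattice units of the central unit,
0 Hz outside.  Each step and each component draws an independent
Gaussian sample around that mean (SD 1).  Noise is injected as a rate
input with one draw per Euler step and no sqrt(dt) scaling — this
matches the discrete-step convention of the model family it extends,
and means spectra are defined relative to the stated dt (1 ms).

Integration: forward Euler, dt = 1 ms, 1.3 s per repeat, all-zero
initial state, first 0.3 s discarded (erases the initialization
transient), 100 repeats per condition by default.  Each repeat draws
its noise from a child stream of the master seed indexed by repeat
number, so runs are exactly reproducible and repeats independent.  A
repeat whose state magnitude exceeds 1e6 is flagged unstable and
frozen rather than left to overflow; the instability threshold is a
guard, not a model feature (strong E->E horizontal coupling or
excitation-dominated feedback genuinely destabilizes the linearized
system — see below).

## Spectral analysis and gamma detection

Power spectra are mean-removed periodograms of each repeat's 1 s
analysis window, averaged across repeats (1 Hz resolution,
density-normalized; every derived statistic is invariant to the
normalization).  The periodogram was chosen over multitaper/Welch
because the protocol already averages 100 independent repeats and the
reported peaks are integer-Hz.

Before peak search the averaged spectrum is smoothed with a 3-bin
Daniell (moving-average) window: the gamma bumps are several bins
wide and the raw argmax otherwise jitters +/- 2 Hz across seeds on a
broad bump.  A band's gamma peak is then the in-band argmax (first
bin on ties), rejected if it sits on either band-end bin.  Peak power is the in-band
maximum minus the mean of the two band-end powers.  Because the
argmax of a peakless noisy band often lands on an interior bin, a
significance criterion stands in for the visual inspection that
traditionally accompanies this rule: the excess of the maximum over
the *chord* joining the band-end powers must exceed z = 3.5 times
chord / sqrt(n_repeats), the relative standard error of an averaged
periodogram bin.  z = 3.5 holds the family-wise false-peak rate near
1% over the ~30-45 bins inspected per band.  The chord reference also
rejects monotone shoulders of a neighbouring peak (a convex flank
stays below its chord).

Band placement.  The classical bands (slow 25-40, fast 45-70 Hz) clip
this model's peaks: the simulated slow gamma sits at 41-46 Hz and the
fast gamma reaches 68-87 Hz.  The package default therefore puts the
slow/fast split at 52 Hz (slow 25-52, fast 52-90), inside the
spectral trough the model actually produces between its two bumps
across all studied conditions; the classical bands and a widened
45-Hz-split variant remain available as presets.  Detected peak
frequencies never equal a band end by construction.

Size-tuning statistics: the suppression index (SI) is peak power at
the largest tested stimulus size divided by the maximum over sizes
(in [0, 1]); the frequency change (FC) is the peak frequency at the
smallest size where the band's gamma exists minus that at the largest
size (positive when the rhythm slows with size).  Both are undefined
— and reported as such — when the peak is absent at the largest size
or present at fewer than two sizes.  Along a swept axis (radius,
coupling), the *onset* of a rhythm is read as the start of the
longest consecutive run of detections, and SI/FC are computed over
that sustained run, which keeps both statistics robust to isolated
false detections at noise level.

## Linear reductions

Replacing H(x) by x and dropping noise, the collective dynamics
compress exactly (FB-only) or approximately (HC-only, wide-kernel
closure) to small linear systems whose eigenvalues classify the
rhythms: a conjugate pair a +/- bi is an oscillation at |b| / 2 pi Hz;
the number of distinct pairs is the number of rhythms the linearized
collective dynamics can support.  A real 3x3 matrix (FB-only: E, I,
G) has at most one pair — feedback alone cannot create a second
gamma.  The 4x4 HC reduction (E_RC, I_RC, E_HC, I_HC) couples the
collective and horizontally-weighted coordinates through the squared
kernel mass 4 sigma^2 W_EE^HC^2 pi^2 = (2 pi sigma W)^2 and the
amplitude ratio alpha = W_EE^HC / W_IE^HC; with the reference
couplings and W_IE^HC = 2.5, W_EE^HC = 0.03 it has two pairs (49.2
and 60.0 Hz), i.e. two distinct oscillations.

Bookkeeping note: the compression must be carried out in mutually
consistent coordinates.  It is easy to over-count the unit number N —
once in the collective coordinate and again in the coupling — which
inflates the cross-coupling products by x225 and destroys the
conjugate pairs entirely (all-real spectra at the two-gamma
exemplar).  The implementation keeps the invariant coupling products
n W_EG W_GE / (tau_E tau_G) for the E-G loop and
(2 pi sigma W_EE^HC)^2 / tau_E^2 for the RC-HC loop.

Scope of the oracle.  The reductions are classifiers, not precision
frequency predictors.  Quantitative (+/- 5 Hz) agreement with the
simulated spectral peak holds where rectification is inactive and the
rhythm is local — the RC-only network (predicted 55.8 Hz, simulated
58-60) — because the noise-driven spectral peak of a damped pair sits
near its undamped frequency sqrt(det), slightly above |b| / 2 pi.  In
feedback and horizontal regimes the central-unit LFP is dominated by
the local resonance while the reduction describes the collective
mode, and in the two-gamma regime rectification is strongly active
(the central E spends much of its time below threshold), so there the
reduction is used at classification level only (how many rhythms),
where it agrees with simulation.  The wide-sigma closure degrades for
narrow kernels; sigma = 4 on a 15 x 15 lattice is within its stated
scope.

## Experiment protocol and problem sizes

The shipped experiments use the full protocol (1.3 s, dt 1 ms, 0.3 s
discard) with these sizes, chosen to pin peak statistics well below
their seed-to-seed variability:

* single conditions (RC-only, RC+HC exemplar): 100 repeats;
* coupling sweeps (W_IE^HC 0-4.5 step 0.25 at W_EE^HC = 0.03;
  feedback grids): 50 repeats per grid point (halves periodogram
  noise relative to the 25-repeat minimum used in scaled-down runs);
* size tuning: integer radii 1-15 (the half-diagonal of the grid is
  ~9.9, so radius >= 10 drives every unit), 50 repeats;
* cross-band SI/FC correlation maps: scaled-down grids (10 HC / 9 FB
  points, 9 radii, 15 repeats) — these estimate rank-correlation
  *signs*, which are stable at this size.

The fully connected exemplar uses W_EG = 0.09 with W_IG = 0.2
(mid-range); both gammas persist under full-field drive there.

## What the generator emulates, and limitations

The synthetic drive reproduces the study conditions: stationary
grating-driven LGN rates with white Gaussian fluctuation.  It does
not emulate temporal structure of real LGN spike trains (refractory
correlations, contrast adaptation), orientation content, or
measurement noise of real LFP electrodes, so passing tests show
internal consistency of the model pipeline, not fidelity to cortical
data.

Behaviours that deviate from the published account of this model
class, found reproducibly in this implementation and documented
rather than tuned away:

* The slow rhythm is born as a 1:2 subharmonic of the fast gamma:
  weak but statistically significant bumps at half the fast-gamma
  frequency appear from W_IE^HC ~ 0.5, and the network mode-locks
  into a strong 41 Hz limit cycle (with an 82 Hz harmonic) around
  W_IE^HC = 1.5-1.75.  Consequently the detected two-gamma regime
  begins around W_IE^HC ~ 0.25-0.5 (published: 0.75) and the
  slow-band power is maximized at W_IE^HC = 1.5-1.75 (published:
  2.5).
  At the exemplar W_IE^HC = 2.5 the slow and fast peaks (44 and
  71 Hz) are mutually independent, as published.
* Feedback modulation: peak-frequency trends match the published
  directions (both bands rise with W_EG, fall with W_IG), but the
  slow-band *power* trend is inverted here (it grows with W_IG):
  in this implementation the slow rhythm is inhibition-driven, so
  extra feedback inhibition deepens it.
* Excitation-dominated feedback (W_EG >~ 0.15 with W_IG = 0) makes
  the linearized network unstable (positive real eigenvalue, runaway
  flagged by the overflow guard); the stated feedback ranges are not
  uniformly stable in this implementation.  The linear reduction
  predicts exactly which corners diverge.

Numerical choices: double precision throughout; simultaneous
(Jacobi-style) state update per Euler step; detection ties resolve to
the lowest frequency; degenerate inputs (all-real spectra, absent
peaks, fewer than three scatter pairs) raise explicit errors or are
reported as undefined rather than coerced.
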