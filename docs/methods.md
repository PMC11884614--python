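# Methods

`idpcrit` quantifies scale-free spatio-temporal correlation in the
conformational dynamics of intrinsically disordered proteins (IDPs) and
similar fluctuating chains.  It implements four analysis stages over
multi-frame coordinate trajectories plus the synthetic generators needed to
exercise them at desk scale.  This note records the models, conventions,
numerical choices and their limits.

## Units and containers

Lengths are nanometres everywhere; PDB Angstroms are converted on I/O.  The
XYZ dialect written and read by this package stores nanometres directly (it
is only used for the package's own one-bead-per-residue chains).  Times are
picoseconds.  Frame intervals are never inferred from coordinate files —
neither PDB nor XYZ carries a reliable clock — so `dt` is a caller option
defaulting to 100 ps, a typical coordinate-saving interval for all-atom MD.
Residue identity in PDB input is the triple (chain id, residue number,
insertion code), renumbered 0-based and contiguous in order of first
appearance.  Residue centers are mass-weighted when the PDB element column
supplies masses and geometric otherwise (missing masses default to 1).

## Temporal correlation: 1/f spectra

The global conformational coordinate is the end-to-end distance R(t), the
center-of-mass distance of the terminal residues (indices overridable).  Its
power spectrum is the one-sided periodogram

    S(f_k) = |DFT(x)|^2 dt / n,   f_k = k/(n dt),  k = 1..n/2,

which by the Wiener–Khinchin theorem equals the discrete Fourier transform of
the biased autocorrelation estimate — the classical "Fourier transform of the
autocorrelation" definition.  The equivalence is a tested contract (an O(n^2)
direct transform of the autocorrelation is the oracle), as is Parseval's
identity.  Conventions:

- **Mean subtraction is on by default.**  The DC offset of a distance series
  otherwise leaks across the low-frequency bins and corrupts the exponent
  fit.  It is a documented switch (`center=False`).
- **No window/taper by default**; optional non-overlapping Welch segmentation
  (`n_segments`) is provided but off.
- Spectra of independent equal-length trajectories are averaged bin-wise.
- Log-binning (default 8 bins/decade, geometric-mean frequency,
  arithmetic-mean power) stabilises the log–log fit.
- The exponent beta is minus the OLS slope of log10 S on log10 f.  The
  default window skips the three lowest bins (poorly averaged) and the top
  half-decade (saving-interval aliasing); both bounds are always recorded in
  the returned `SpectralFit` and user-overridable.

beta = 0 is white noise, beta = 2 Brownian noise; beta near 1 ("1/f noise")
signals scale-free temporal correlation.

## Spatial correlation: residue domains

Two residues are in contact when any inter-atom distance is strictly below
0.35 nm, excluding sequence neighbours (|i-j| <= 1).  A residue domain is a
connected component of the 2-core of the per-frame contact graph — every
member keeps at least two within-domain contacts — and only components with
at least 5 residues ("size exceeding 4", strict reading) are retained.
"Separate 2-core" is interpreted as connected components of the global
2-core; a component of a 2-core is itself a 2-core, and this reading keeps
domains disjoint.  The largest domain per frame is the dominant domain; when
several tie, all count as dominant for involvement statistics (avoiding
index-order bias).

Domain sizes pooled over frames are fitted as P(s) ~ s^-tau by least squares
on the log-binned probability mass function over [5, 0.3 N] (default),
avoiding the finite-size tail.  Because sizes are integers, each log bin's
ordinate is the *average mass per integer size it covers*; dividing by the
continuous bin width instead biases tau upward by ~0.2 at small s where a
bin holds one or two integers.  A discrete (Hurwitz-zeta) maximum-likelihood
estimate is shipped as a cross-check; it ignores the upper truncation and
therefore over-estimates tau on strongly finite-size-cut samples — it is not
the default.

Finite-size scaling writes P(s, N) ~ s^-tau G(s/N).  `scaling_collapse` maps
each distribution to (s/N, P(s) s^tau) after log-binning and after
normalising each curve's maximum to one.  The max-normalisation matters:
near tau = 1 the probability normalisation constant of a truncated power law
varies with N like N^(tau-1), which offsets probability-normalised curves
vertically even at the true exponent (numerically, the plain-pmf score
prefers tau_true + 0.5).  The collapse score is the mean squared
log10-difference of the curves from their pointwise mean over a common
log-spaced grid of s/N covered by all curves; 0 for identical curves.

Domain compactness follows from Rg ~ s^(1/d_f): d_f is the reciprocal OLS
slope of log Rg versus log s over all retained domains (residue-center Rg,
unit weights).  The fit is refused — result carries `None` plus a reason —
with fewer than 10 domains or less than half a decade of size span.
Reference values: d_f = 1 for rods, ~2 for random-walk-like objects, 3 for
compact bodies.

The involvement profile is the per-residue fraction of frames spent in the
dominant domain (frames without domains count in the denominator), and the
domain-prone region is the contiguous window of length round(N/3) maximising
mean involvement (ties resolved toward the smallest start; window length
chosen because published domain-prone spans are N/3 windows).

## Collective motion: C(r) and the correlation length

Frames t and t+1 are superposed by an all-atom Kabsch fit (proper rotation
enforced; `scipy.spatial.transform.Rotation.align_vectors` is the backend) to
remove whole-molecule translation and rotation; residue velocities are the
residual residue-center displacements over dt.  For every consecutive frame
pair and residue pair i < j, the cosine similarity of the two velocities is
accumulated in a bin of the residue-center distance r_ij measured in the
earlier frame (default bin width 0.1 nm).  C(r) per bin is the average
contribution.  Normalisation is per frame-pair (cosine) by default; the
bracketing of the defining ratio is ambiguous, so a global mode (binned mean
dot product over global mean squared speed) is available via
`normalize="global"`.  Residues slower than 1e-13 nm/ps are treated as at
rest (Kabsch rounding noise) and skipped with a count; a trajectory whose
every velocity field is null raises an error suggesting a larger dt.

The correlation length xi is the first positive-to-non-positive zero
crossing of C(r), linearly interpolated between the bracketing bins; a curve
with no crossing yields `None` rather than an exception.  Rescaling to
x = r/xi puts the crossing at x = 1 by construction.

## FRET conversion

Transfer efficiency and inter-dye distance are related by
E = 1/(1 + (R/R0)^6) with Förster radius R0 = 5 nm by default (typical of a
Cy3/Alexa-647 pair).  Efficiencies are clamped into (0.01, 0.99)
(configurable, clamped points countable) before inversion, since the map is
non-invertible at 0/1 and shot noise exceeds those bounds in real traces.
Intensity traces convert via E = I_A/(I_A + gamma I_D), gamma defaulting
to 1; zero-total points are masked and counted.  Distance series derived
from traces run through the identical spectral machinery; equal-length
traces are bin-averaged before the headline fit, unequal-length sets fall
back to per-trace fits with the pooled mean +/- SD of beta (flagged by
`averaged=False`).

## Synthetic generators (what they emulate, what they do not)

All generators are bit-reproducible under (seed, parameters).

**Colored noise** — spectral synthesis: Fourier amplitudes proportional to
f^(-beta/2) with i.i.d. uniform phases, Hermitian symmetry, inverse
transform, standardised to zero mean and unit variance.  The amplitude
profile is deterministic, so single realisations have exactly power-law
periodograms; this makes estimator checks sharp but does not emulate the
chi-squared bin scatter of a stochastic-process periodogram.

**HP heteropolymer** — the near-theta-point control: L beads (default 73),
floor(frac_H L) hydrophobic at uniformly random positions (36 at the
defaults; the floor rule fixes the count deterministically).  Potential:
harmonic bonds U_b = k(r-b)^2/2 plus an Ashbaugh–Hatch lambda-scaled
Lennard-Jones for |i-j| >= 2 — inside the LJ minimum the full LJ shifted up
by (1-lambda) eps, outside it lambda times the LJ tail, with
lambda_pair = (lambda_i + lambda_j)/2; purely repulsive (WCA) at lambda = 0.
Dynamics: underdamped Langevin, BAOAB splitting.  The published
coarse-grained parameter set for this control lives in unavailable
supporting material, so the simulator is *parameterized, not calibrated*;
defaults are HPS-flavoured and chosen once:

| parameter | default | why |
|---|---|---|
| bond_k | 500 kJ/mol/nm^2 | stiff CG bond; omega dt ~ 0.09 |
| bond_b | 0.38 nm | Calpha-Calpha spacing |
| lj_sigma | 0.45 nm | residue-scale bead |
| lj_epsilon | 1 kJ/mol (~0.4 kT) | weak attraction: coil near theta |
| lambda_H / lambda_P | 1 / 0 | hydrophobic attractive, polar repulsive |
| temperature | 300 K | ambient |
| mass | 1 amu | reduced-ish units; speed over realism |
| friction | 0.5 /ps | ~critical damping of the slowest Rouse mode, fastest conformational sampling |
| timestep | 0.002 ps | resolves LJ collisions at unit mass (collision time ~0.03 ps); 0.01 ps is unstable |
| cutoff | 3 sigma | tail negligible beyond |

At these defaults a 73-bead chain has mean end-to-end distance ~6 nm and an
end-to-end relaxation time of ~6 ps, so a 1000 ps run (500k steps, ~15 s on
one core) provides >150 independent conformational samples.  Consequences a
user should expect and tests rely on: the end-to-end spectrum is
Lorentzian-like — a high-frequency rolloff above ~0.03/ps and a white
plateau below — so its low-frequency exponent is far below 1, the
qualitative signature distinguishing a generic heteropolymer from 1/f
dynamics.  The simulator makes no claim of reproducing any published
spectral exponent value.  Non-finite coordinates abort with the failing step
named; a gradient-descent quench mode (backtracking line search, provably
non-increasing energy) supports integrator sanity checks.

**Planted-domain conformers** — cluster members are placed in a ball of
diameter `intra_cluster_scale` (< contact cutoff, so all non-neighbour pairs
are mutually in contact), cluster centers `cluster_spacing` apart
(> 2 cutoffs), remaining residues on a distant arc with no contacts at all;
the construction self-validates before returning.  These give exact ground
truth for detection, not realistic chain geometry.

**Power-law sizes** — inverse-CDF draws from p(s) proportional to s^-tau on
an integer interval.  **Gaussian chains** — i.i.d. isotropic Gaussian bonds
with RMS length b (ideal-chain null: <R_ee^2> = (N-1) b^2, d_f = 2).
**Hinge motions** — two mirror-symmetric compact blocks counter-translating
along x; the displacement field has zero net translation and zero net
angular momentum, so rigid-body alignment is provably neutral and the C(r)
sign structure (positive intra-block, negative inter-block) is exact ground
truth.

## Pipeline

`run_pipeline` executes requested stages in dependency order from one
declarative config (YAML or `RunConfig`); every analysis constant lives in
the config with the defaults above, never hard-coded, so the same pipeline
applies unchanged to other trajectories (e.g. different solvent conditions).
Outputs are per-stage TSVs plus `summary.json`/`summary.tsv` with
fixed-precision formatting and sorted keys: identical config + seeds give
byte-identical summaries.  A stage failure aborts with the stage named and a
`FAILED` marker; completed outputs are retained.

## What a green test establishes — and does not

The validation strategy is property-based: exact oracles (brute-force DFT,
peeling fixed points, exhaustive scans), planted ground truth, closed forms
(ideal chain, uniform ball, chi distribution, Boltzmann quadrature) and
generator/estimator consistency.  Green tests establish that every operator
implements its stated mathematical contract at desk scale.  They do *not*
establish the headline physics (beta ~ 1 over three decades, tau ~ 1.15,
d_f ~ 2, xi of 1.7-2.2 nm, <E> ~ 0.63-0.67): those quantities require
microsecond all-atom trajectories and single-molecule recordings that cannot
be regenerated here, and no test asserts them.  The heteropolymer control is
asserted qualitatively only (low-frequency exponent < 0.8 and below a
matched 1/f reference), because the published control's parameterization is
unavailable.

## Known limitations

- No binary trajectory formats (XTC/DCD), PBC unwrapping, or topology files.
- The spectral estimator assumes uniform sampling; no multitaper option.
- The discrete-MLE tau cross-check ignores upper truncation (documented).
- `correlation_function` pools consecutive frame pairs only (no lag sweep).
- The HP model's units are internally consistent (nm, kJ/mol, ps, amu) but
  not matched to any specific published CG force field.
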