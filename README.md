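# idpcrit

Scale-free spatio-temporal correlation analysis for conformational
trajectories of intrinsically disordered proteins (IDPs) and other
fluctuating chains.

IDPs lack a fixed native structure and wander continuously through
conformational space.  Near a critical point, such dynamics leave two
signatures: *temporal* scale-freeness — the power spectrum of a global
coordinate like the end-to-end distance R(t) follows S(f) ∝ f^(−β) with
β ≈ 1 ("1/f noise", between white β=0 and Brownian β=2) — and *spatial*
scale-freeness — transient "residue domains" (clusters of mutually
contacting residues) whose sizes s follow P(s) ∝ s^(−τ) with a finite-size
cutoff, P(s, N) ∼ s^(−τ) G(s/N).  `idpcrit` computes both, plus the
distance-binned velocity correlation C(r) with its correlation length ξ
(the first zero crossing), the fractal dimension d_f from R_g ∼ s^(1/d_f),
per-residue dominant-domain involvement profiles, and FRET
efficiency↔distance conversion E = 1/(1 + (R/R₀)⁶) so single-molecule traces
run through the same spectral machinery.

Audience: structural and computational biophysicists with multi-frame
coordinate data (multi-MODEL PDB, or the package's nm-dialect XYZ for
coarse-grained chains), scalar time series, or FRET efficiency traces.

## What is inside

| module | contents |
|---|---|
| `idpcrit.io` | trajectory/time-series containers, PDB/XYZ/TSV readers and writers, residue centers, end-to-end series, radius of gyration |
| `idpcrit.spectral` | autocorrelation, periodogram (Wiener–Khinchin route), spectrum averaging, log-binning, β fits |
| `idpcrit.domains` | contact graphs (0.35 nm all-atom cutoff, sequence neighbours excluded), 2-core domain decomposition, τ fits, finite-size scaling collapse, d_f, involvement profiles, domain-prone regions |
| `idpcrit.motion` | Kabsch alignment, residue velocity fields, C(r), correlation length ξ, rescaled curves |
| `idpcrit.fret` | efficiency↔distance maps, trace readers, trace spectra, simulation-side mean efficiencies |
| `idpcrit.synthetic` | colored noise with prescribed β, HP heteropolymer Langevin simulator (BAOAB, Ashbaugh–Hatch potential), planted-domain conformers, power-law sizes, Gaussian chains, hinge motions |
| `idpcrit.pipeline` / `idpcrit.cli` | single-config end-to-end runs, `idpcrit` command with per-stage subcommands |

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

```python
import numpy as np
import idpcrit as ic

# A coarse-grained heteropolymer control: 73 beads, half hydrophobic.
seq = ic.generate_hp_sequences(L=73, frac_H=0.5, n=1, seed=42)[0]
traj = ic.simulate_hp_polymer(seq, n_steps=150_000, save_every=50, seed=42)

# Temporal correlation: spectrum of the end-to-end distance.
ree = ic.end_to_end_series(traj)
fit = ic.fit_exponent(ic.log_bin(ic.power_spectrum(ree), 8))
print(f"mean Ree {np.mean(ree.values):.2f} nm, beta {fit.beta:.2f} "
      f"(r^2 {fit.r_squared:.2f})")

# Spatial correlation: residue domains (bead-distance contacts at 0.6 nm).
decomps = [ic.decompose_domains(f, cutoff=0.6, frame_index=k)
           for k, f in enumerate(traj.frames)]
dist = ic.size_distribution(decomps, N=traj.n_residues)
print(f"{dist.n_domains} domains, tau_hat {dist.tau_hat:.2f}")

# Collective motion: velocity correlation length.
curve = ic.correlation_function(traj, bin_width=0.1)
print(f"xi {curve.xi:.2f} nm")
```

Output (seed 42):

```
mean Ree 5.04 nm, beta 1.47 (r^2 0.87)
3102 domains, tau_hat 2.50
xi 0.54 nm
```

Reading the numbers: the steep default-window β reflects the chain's
high-frequency Lorentzian rolloff — fitting *below* the chain relaxation
rate, `ic.fit_exponent(ic.log_bin(ic.power_spectrum(ree), 8), f_min=0.002,
f_max=0.03)`, gives β = −0.29, the white-noise plateau that distinguishes a
generic heteropolymer from 1/f dynamics.  The steep τ and short ξ likewise
say this chain has no scale-free domain structure — exactly the expected
contrast with IDP trajectories.

The same analyses run from the shell:

```sh
idpcrit run --config run.yaml          # full pipeline from one YAML config
idpcrit spectrum series.tsv --fmin 1e-3 --fmax 1e-1
idpcrit domains traj.pdb --cutoff 0.35 --min-size 5
idpcrit correlation traj.pdb --bin-width 0.1
idpcrit fret trace.tsv --r0 5.0
idpcrit simulate-polymer --length 73 --n-chains 10 --seed 1
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch: it generates a
73-bead heteropolymer trajectory, runs spectrum/domain/involvement/
correlation stages on it, runs a colored-noise spectral-exponent recovery
pass, logs the stage summaries to stderr and writes the results JSON to
`--out`.
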