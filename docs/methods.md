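# Methods

## Connector elasticity

Connectors are inextensible worm-like chains. We use the Marko–Siggia
force–extension interpolation, F(z) = (kBT/Lp)·[¼(1−z/Lc)⁻² − ¼ + z/Lc],
because it is the standard single-parameter-family WLC closed form, is exact
in both force limits, and is analytically differentiable and integrable, so
force, stiffness and elastic energy stay mutually consistent to machine
precision. Extension is clamped strictly below Lc (relative margin 1e-12);
fully extended duplexes are handled by the actuator's rigid-rod mode, not by
the WLC functions. The numeric inverse (extension at force) uses bracketed
Brent root finding to 1e-12 nm.

Parameter defaults and units:

| parameter | default | unit | rationale |
|---|---|---|---|
| ssDNA rise | 0.63 | nm/nt | literature convention for stretched ssDNA |
| ssDNA Lp | 1.0 | nm | reported value for these connectors |
| dsDNA rise | 0.34 | nm/bp | fixed by 97 bp → 33 nm anticipated travel |
| dsDNA Lp | 50.0 | nm | B-DNA above ~10 mM Na⁺ |
| temperature | 296.15 | K | device characterized at 23 °C |
| k_B | 0.0138065 | pN·nm/K | unit system pN/nm/pN·nm |

Lp is a plain parameter; no salt dependence is modelled. The small-extension
behaviour is the linear entropic spring F ≈ 3kBT/(2·Lp·Lc)·z; the exact
deviation ratio is 1 + u/2 + 2u²/3 with u = z/Lc, i.e. 5% is reached at
u ≈ 0.085 and 5.07% as u → 0.1. Tests assert the exact series bound.

## Actuator force balance

A single coordinate x (piston-bottom to cylinder-bottom distance) maps to
both connector sets: e_top = x + c₁, e_bot = D − x + c₂ with a conserved
end-to-end budget D. The total potential adds n-fold WLC energies per side
and a harmonic protein spring; its unique minimum (the potential is convex,
verified numerically before each solve) is found as a bracketed root of the
analytic gradient, with equilibrium residual below 1e-6 pN.

Two modelling choices the geometry forces:

* **Slack tethers.** Loop connectors cannot push. Nominal extension ≤ 0
  contributes zero force and energy. This keeps U convex and C¹ (the WLC
  force vanishes at zero extension) and is required for the calibration
  below to have an interior solution: with a hard e ≥ 0 constraint the two
  published operating points cannot be met simultaneously (the fit residual
  bottoms out at ~0.24 pN on the constraint boundary).
* **Calibrated geometry.** The published design does not pin (D, c₁). They
  are fit once, by least squares over full equilibrium solves, to the two
  published operating points — 1.6 pN delivered at k_protein = 0.1 pN/nm and
  30 pN at 20 pN/nm for the 97-nt autonomous device with six connectors per
  side — and frozen as package defaults (D = 31.7189 nm, c₁ = −2.1356 nm,
  c₂ = 0). The calibration reproduces both points to < 1e-9 pN and is
  re-derivable at run time (`calibrate_geometry`). With these defaults the
  free equilibrium sits at 16.9 nm, consistent with the measured mean
  distance of the same device.

Remote activation has two sub-models. The rigid-rod mode places the piston
at full duplex contour length (travel = round(n_bp × 0.34 nm): 10/20/33 nm
for 30/60/97 bp); it is the model behind the "anticipated distance" numbers.
The effective-spring mode replaces the top WLC term with
½·k_eff·(e_top − Lc)², using the coarse-grained-simulation stiffness
k_eff = 8.0 pN/nm (ds) as a device-level constant (3.0 pN/nm for ss); those
stiffnesses are inputs here, not re-derived. Note a geometric consequence of
the shared coordinate: a taut bottom tether pulls x up, so the
effective-spring equilibrium sits slightly *above* Lc (by n·F_bot/k_eff,
~1.2 nm for the default remote geometry), while the sub-contour mean
distances observed for real duplex connectors (31.3 vs 33 nm at 97 bp) arise
from thermal bending, i.e. from the full-WLC route, not the harmonic one.
The default remote geometry leaves the bottom ss connectors 15 nm of
extension at full ratchet — a package choice, as the remote-mode frame is
not otherwise pinned.

Auxiliary quantities: the hairpin benchmark force is the linear estimate
k_eff × deformation (8.0 pN/nm × 5.3 nm ≈ 42 pN, above the hairpin's
F1/2 ≈ 20 pN); hairpin opening is a two-state logistic in the opening work
with width Δz = 10 nm (a typical hairpin opening distance; configurable);
membrane indentation is linear at 0.1 nm/pN; the positioning spread of n
parallel connectors of per-connector stiffness k is the equipartition SD
√(kBT/(n·k)).

## Thermal ensemble

The piston ensemble is 1-D Boltzmann over x: the TEM observable is a 1-D
distance, and tilt/rotation of cylinder vs. backstop are excluded (their
neglect likely makes the effective stiffness an overestimate; recorded, not
modelled). Moments come from adaptive quadrature of exp(−(U−Umin)/kBT)
(normalization to better than 1e-8 relative); quantiles and histograms from
a dense trapezoid CDF at 0.05 nm resolution. The stochastic twin is a
Metropolis chain with Gaussian proposals (default 1 nm), reflective
boundaries at the admissible range, 10% burn-in, and a mandatory explicit
seed; the acceptance rate is recorded and warned on outside [5%, 95%].
Monte-Carlo standard errors are computed by batch means (50 batches), which
accounts for chain autocorrelation; "within 3 SE" agreement checks between
the two routes use these SEs.

## TEM distances

Distance tables are CSV (`distance_nm[,label]`); parsing rejects negative
or non-numeric rows by row index. The measured r maps to actuation distance
d through an explicit affine map defaulting to the identity (the two are
directly correlated; any offset is a configuration parameter, never a hidden
constant). Summaries use the unbiased (n−1) sd, 5/50/95% quantiles, and a
density histogram with 2 nm default bins. Comparisons against model
ensembles report the mean difference, sd ratio and KS statistic only — the
ensemble is a model of thermal motion, not a fit to TEM spreads, which also
contain staining/drying artefacts.

## Readouts

*Bead calibration* regresses log10(molecules/bead) on log10(MFI) (base
configurable) and converts background-subtracted cell MFI through the line.
*LRET reduction* computes R = scale·I665/I620 per well (scale 1e4, matching
the magnitude convention of the printed ratios), subtracts the mean
antibody-only background R0, and reports per-condition mean ± sd over
replicate wells; scaling before subtraction is the default and the order is
exposed. *Trace idealization* splits current values by a deterministic 1-D
2-means (5th/95th-percentile initialization), tracks states through a
midpoint threshold with a hysteresis band of ±¼ of the level separation,
merges dwells shorter than 5 samples (shortest first), and recomputes
per-state statistics from the final assignment. A threshold idealizer, not
an HMM, is used deliberately: the reported levels are 3 noise-sd apart,
where hysteresis plus dwell merging already assigns > 99.9% of samples
correctly on synthetic benchmarks, and the method stays transparent. The
unimodality guard (level separation < 2× pooled within-level sd → single
state) fires for constant or quantized traces; for Gaussian-dominated noise
a 2-means split always yields separation ≈ 1.6σ against a 1.2σ threshold, so
genuinely unimodal noisy traces are not caught by this rule — a known
limitation of the rule itself.

## Synthetic data

Generators mirror the study conditions and are the package's fixtures:

* TEM distances: truncated normal on [0, ∞). Default means 17.7/14.0/9.3 nm
  (ss 97/60/30 nt) and 10.7/19.0/31.3 nm (ds 30/60/97 bp); sd 5 nm is a
  fixture convention chosen to match the visual spread of the published
  distributions (per-variant sds are not printed).
* Bead tables: five populations at 10²–10⁶ molecules/bead on an exact
  log-log line, lognormal multiplicative MFI noise (unit mean), cv 5%
  default; three replicate cell MFIs at a configured true count
  (default 9,200/cell).
* LRET plates: donor level 1e4 counts, background ratio R0 = 1.0e4 (a
  realistic plate-reader background magnitude), configured true response
  (default 1.23e4), independent multiplicative noise (cv 10%) on both
  channels, three wells per condition.
* Channel traces: two-state continuous-time Markov chain, closed 4 pA /
  open 16 pA, Gaussian noise sd 4 pA, 1 kHz, 60 s, mean dwells 1 s per
  state (second-scale gating, matching the reported recordings).

Every generator is seeded and exactly reproducible; file writers emit a
JSON sidecar (generator, parameters, seed, version) from which the CSV can
be regenerated byte-identically. What passing recovery tests show is that
the *reduction pipelines* are unbiased and correctly scaled at realistic
noise levels — not that real TEM images, cytometer optics or bilayer
recordings are this clean; real data add baseline drift, autofluorescence,
image-processing error and non-Gaussian noise that these generators do not
emulate.

## Problem sizes and determinism

Shipped defaults: quadrature grids at 0.05 nm; Metropolis chains of
5×10⁴–10⁵ steps (agreement checks use batch-means SEs); TEM recovery at
n = 500 (plus 10⁴ for generator checks); 60 s traces at 1 kHz; 100
replicate bead pipelines for the bias check. These sizes put every
stochastic check several SEs away from its tolerance while keeping the
whole suite fast. All test seeds are fixed constants; the acceptance script
derives independent substreams from its single `--seed` argument via
`SeedSequence.spawn`.

## Known limitations

One mechanical coordinate (no tilt, torsion or leg bending — the legs'
micron-scale persistence length justifies rigidity); no sequence-dependent
elasticity, twist or salt-dependent Lp; no kinetics (the ensemble has no
friction model, so dwell times of the piston are out of scope); membrane
mechanics reduced to a linear indentation coefficient; trace idealization
is two-level only and assumes a drift-free baseline.
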