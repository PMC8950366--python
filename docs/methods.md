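# Methods

## The discriminant

CYP oxidation chemistry happens at the heme iron, so the distance between a
ligand's reactive atom (the site of hydroxylation or demethylation) and that
iron, tracked over a trajectory, is a direct structural proxy for whether a
catalytically competent pose is held. `hemedist` treats the per-frame
distance series `d(t)` as the primary observable and derives everything else
from it:

- the per-complex **mean ± SE** in nm;
- pairwise **t-tests** between a variant complex and the reference allele;
- a **detachment** call — the first run of consecutive frames above a
  threshold lasting at least a persistence window;
- a **substrate-likelihood** label relative to the probe-substrate envelope;
- a **variant-effect** label (a significantly lower mean distance than the
  reference allele is read as likely-enhanced metabolism, a higher one as
  likely-reduced).

The approach is deliberately semi-quantitative: it ranks complexes and flags
qualitative differences; it does not estimate rate constants or binding free
energies.

## Geometry

Structures and trajectories live in Å internally (PDB native); every
reported distance or RMSD is converted to nm at the reporting boundary.
Superposition is the Kabsch algorithm via SVD, mass-unweighted, with a
determinant correction so reflections are never returned. RMSD series use
frame 0 as the reference (inputs are assumed post-equilibration;
configurable). Two RMSD modes are provided: protein C-alpha (superpose and
analyse C-alpha) and ligand-in-protein-frame (superpose on C-alpha, analyse
ligand atoms), the latter because a drifting ligand should register even
when the protein scaffold is rigid. Ligand self-superposed RMSD would hide
exactly that signal, which is why it is not the default.

Residues keep author numbering everywhere. Mutation positions (e.g. 445)
are interpreted in that numbering; `apply_mutations` verifies the expected
wild-type residue at every position before touching the sequence, so a
numbering drift fails loudly rather than silently mutating the wrong site.

## Statistics

**SE convention.** `summarize` reports SE = SD/√n over frames, treating
frames as independent. This matches the convention under which MD frame
statistics such as "0.439 ± 0.002 nm over 5000 frames" are reported, and is
the default for comparability. It is *not* statistically honest for
autocorrelated frames: with a mean-reversion time of 20 ps sampled every
10 ps, the true variance of the sample mean is ≈4× the naive estimate. Both
`summarize` and `compare` therefore accept an `ess_correction` flag that
rescales by the effective sample size `n_eff = n / (1 + 2·Σρ_k)`
(initial-positive-sequence estimator of the integrated autocorrelation
time). The flag is off by default; the reporting convention comes first,
the correction is available where calibrated inference matters.

**t-tests.** `compare` is an independent two-sample t-test on per-frame
values: pooled-variance Student (df = nA+nB−2) by default, Welch
(Satterthwaite df) as a flag, two-sided p-values, α = 0.05. Direction is the
sign of the mean difference, reported only when significant. Degenerate
zero-variance pairs have a documented contract (equal means → p = 1,
different means → p = 0). No multiple-testing correction is applied across
complex pairs; the per-pair p-values in the default scenarios are so far
below any threshold that correction would not change a call, but users
comparing many marginal pairs should correct externally.

**Calibration.** Under the null (identical OU parameters) the naive
frame-wise test is calibrated only when frame coupling is weak: its
empirical size stays below 0.10 at lag-1 autocorrelation ≈0.05, but inflates
to ≈0.3 at the preset-like autocorrelation (θ = 0.05/ps, dt = 10 ps). The
ESS-corrected test stays below 0.10 in both regimes. The test suite pins
both facts; this is the quantitative reason the correction exists.

**Batch means.** `batch_means_se` (50 contiguous batches by default) gives a
consistent SE for autocorrelated series — batch length 1 ns ≫ the 20 ps
autocorrelation time at default settings — and is what parameter-recovery
checks use as their yardstick.

## Detachment

`detect_detachment` calls an onset at the start of the first run of frames
all strictly above `threshold_nm` (default 0.6 nm) lasting at least
`window_ps` (default 1000 ps). The defaults separate the stable complexes
(stationary means 0.41–0.54 nm, SD ≈ 0.07 nm: excursions above 0.6 nm are
short) from detached regimes (means ≥ 0.6 nm). Both are configurable; a
series whose stationary mean already sits above the threshold will report an
onset near t = 0, which is the intended reading ("never attached").

## Substrate and variant calls

The probe envelope is the largest mean distance among the probe substrates'
reference-allele complexes (dextromethorphan and bufuralol by default).
Margins above the envelope: ≤ +0.05 nm → `probe_like`; ≤ +0.15 nm →
`minor_substrate`; beyond → `poor_or_non_substrate`. The margins are
calibrated once so that the shipped scenario means map onto their
qualitative descriptions (probes probe-like; OTA wild type a minor
substrate; the detached dextromethorphan-\*51 complex poor/non). They are
parameters, not discoveries; anyone applying the pipeline to other chemistry
should treat them as tunable.

ΔΔG stability uses a strict inequality: ΔΔG < 1 kcal/mol →
`limited_effect`, ΔΔG ≥ 1 → `potentially_destabilising`; the boundary value
1.0 is classed destabilising. Mutation-site proximity to the iron uses a
1.0 nm minimum-atom-distance cut-off ("proximal"/"distal"), a heme-pocket
length scale; the cut-off is configurable and the annotation is descriptive
only.

## Synthetic data: what it emulates and what it does not

No deposited trajectories exist for these complexes, so the generator
emulates the *statistical* structure of the distance signal, not its
physics:

- **OU process, exact discretisation.**
  `x(t+dt) = μ + (x(t) − μ)·e^(−θ·dt) + σ·√((1 − e^(−2θ·dt))/(2θ))·z`.
  Mean-reverting, Gaussian, stationary SD σ/√(2θ) — a reasonable stand-in
  for a bound ligand fluctuating about a pose. Values are floored at 0.15 nm
  (hard-sphere contact) on the output only, so the recursion stays exact;
  flooring events are logged.
- **Presets.** θ = 0.05/ps everywhere (20 ps relaxation — fast pose
  dynamics relative to the 10 ps frame spacing). Stationary means are the
  reported per-complex values. σ is set per preset so the stationary SD
  equals the complex's reported SE × √5000 — reproducing each printed SE
  under the naive SD/√n convention — capped at (μ − 0.15)/3.5 so the
  contact floor sits ≥3.5 SD below the mean and flooring stays below 0.1% of
  frames (the two complexes with ±0.002/0.003 nm SEs at small means hit the
  cap). The OTA:\*122 scenario has no reported mean; it uses a regime switch
  at 5 ns (early relative to a 50 ns run) to a detached mean of 1.0 nm.
- **Trajectory embedding** places the ligand rigidly each frame so the
  Fe–reactive-atom distance equals the series exactly, with optional
  Gaussian jitter on protein atoms only. This gives full-pipeline tests a
  ground truth that survives a multi-model PDB round trip to format
  precision (±0.5 mÅ per coordinate).
- **MSA generator** produces gapless alignments with an exactly controlled
  substitution count at one reference-mapped column and i.i.d. background
  mutation elsewhere (default background identity 0.95).

What the generator does **not** emulate: force-field physics, solvent,
binding/unbinding kinetics beyond a single regime switch, correlated
protein–ligand motion, alignment gaps, or phylogenetic structure among
homologs. Passing tests therefore demonstrate that the *analysis* recovers
known statistical structure — means, orderings, onsets, counts — not that
the underlying MD or alignment biology is reproduced.

## Problem sizes and numerical choices

Default analyses use 5000 frames at 10 ps spacing (a 50 ns span); the
package's own test fixtures use 100–600 frames for structural round trips
and full-pipeline checks, and 5000 frames where parameter recovery is the
point. Column and residue positions are 1-based throughout. Gap-holding
sequences are excluded from both numerator and denominator of conservation
by default (`count_gaps` flips this); conservation is reported both as an
exact fraction and as an integer-rounded percentage. Motif hits may overlap;
the scanner checks every window. Kabsch requires ≥3 non-collinear points;
distance series reject identical atom indices and log coincident-atom
frames. All generators and the pipeline derive per-scenario seeds from one
global seed (`numpy.random.SeedSequence`), making reports byte-identical
across reruns of the same config.

## Known limitations

- The discriminant ignores orientation: a reactive atom can be near the iron
  in a non-productive geometry. Distance is a necessary-not-sufficient proxy.
- Calls inherit the margins/thresholds above; they are calibrated to this
  chemistry's length scales and should be revisited for other enzyme–ligand
  systems.
- The naive SE convention understates uncertainty for correlated frames (see
  Statistics); conclusions that hinge on borderline significance should use
  `ess_correction=True`.
- Sequence-level variant bookkeeping does not rebuild side chains; structural
  consequences of a mutation enter only through supplied structures or the
  synthetic stand-ins.
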