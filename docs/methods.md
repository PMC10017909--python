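# Methods

`dhpmd` implements the computational half of a compressibility-perturbation
strategy for engineering solvent-tolerant enzymes: simulate a protein across
a pressure × ethanol condition grid, find the regions whose volume
fluctuations respond most strongly to the conditions, saturate those regions
with virtual mutations, and keep the mutants that two independent stability
predictors agree on. The package consumes trajectory snapshots (it does not
run MD itself) and provides synthetic generators so that every stage is
testable without external simulation output.

## Isothermal compressibility from volume fluctuations

At equilibrium the variance of a subsystem's volume is tied to its
isothermal compressibility by

    ⟨δV²⟩ = k_B · T · ⟨V⟩ · β_T

so `beta_T` estimates β_T = Var(V) / (k_B·T·⟨V⟩). Variances use the
population convention (divide by n), matching the ensemble average in the
relation; `ddof=1` is available. The unit chain is Å³ in, bar⁻¹ out
(1 Å³ = 10⁻³⁰ m³; 1 bar = 10⁵ Pa; k_B = 1.380649×10⁻²³ J/K exact). A series
of {990, 1000, 1010} Å³ at 313 K therefore gives β_T ≈ 1.543×10⁻⁶ bar⁻¹,
which the tests pin against an independently coded unit chain.

The estimator's sampling error is that of a variance: relative standard
error ≈ √(2/n). Thirty 1-ns samples (one 30-ns run) give ≈26 % noise on a
single estimate; the pipeline therefore pools parallels by concatenating
their volume samples before estimating.

## Per-region volumes by periodic Voronoi tessellation

Space is partitioned by the ordinary (unweighted) Voronoi tessellation of
all atomic sites — radii enter SASA, not the volume partition — and a
region's volume is the sum of its heavy atoms' cells, with solvent included
in the tessellation so protein–solvent boundaries are physical. Cell volumes
sum to the box volume exactly, which is the standing conservation test.

Periodicity is realised by explicit 3×3×3 image tiling. Two certified
shortcuts keep trajectory analysis fast without changing results:

- image points farther than min(box)/2 from the box are pruned before
  tessellating;
- when only a small subset of cells is requested (the usual per-region
  case), each cell is built from its periodic neighbourhood alone, growing
  the search radius geometrically.

Both paths carry the same validity certificate: a face of site *s*'s cell
can only be contributed by a site within twice the cell's circumradius, so
if 2·r_circum ≤ the pruning margin (or search radius) no discarded point
could have mattered. Cells failing the certificate are recomputed on the
full 27-image tiling. Degenerate pruned clouds (e.g. collinear sites) also
fall back. Coincident sites are an error naming the pair.

## Region partitioning

Residues are classified helix/sheet/loop either from an external
one-letter-per-residue file (H/E/C) — the auditable route — or from a
built-in backbone-dihedral window heuristic: helix for φ ∈ [−100°, −30°] and
ψ ∈ [−80°, −5°], sheet for φ ∈ [−180°, −80°] and ψ ∈ [80°, 180°], loop
otherwise. Chain termini are classified on their single defined angle. Helix
runs shorter than 4 and sheet runs shorter than 3 residues are reclassified
as loop. Segments are named `class_start-end` with 1-based inclusive bounds
(`loop_67-76` has ten residues).

## Sensitivity ranking

Each region × condition cell gets a β_T estimate; a region's sensitivity
score is the absolute range (max − min) of its β_T across the grid, in
bar⁻¹, with a relative (range/mean) variant behind a flag. Ranking is
descending by score with alphabetical tie-break, and a region missing some
conditions is scored on what it has, with a recorded warning.

## Virtual saturation and the consensus filter

Selected regions are saturated with all 19 substitutions per position
(ordered by position, then mutant letter). Each candidate carries two
predicted ΔΔG values with opposite sign conventions — slot A negative =
stabilising (FoldX-style), slot B positive = stabilising (I-mutant-style) —
normally read from a TSV produced by external predictors. The consensus
verdict is `stabilizing` iff ΔΔG_A < 0 **and** ΔΔG_B > 0, strictly; a
candidate missing either score is `incomplete` and never stabilising. The
filter is monotone in both scores.

For hermetic end-to-end runs a surrogate scorer produces deterministic
pseudo-scores from weighted differences of Kyte–Doolittle hydropathy,
residue volume and helix propensity plus seeded Gaussian noise. It is a
stated heuristic for plumbing only — not a reimplementation or approximation
of either external predictor — and its outputs should never be interpreted
energetically.

## Trajectory flexibility analysis

Frames are superposed on a reference (default: first frame) over a selection
(default: Cα) by the optimal proper rotation + translation; RMSD is computed
over the selection per frame and RMSF per residue as the root-mean-square
deviation from each atom's time-mean position (population mean, unweighted;
residues aggregate either the Cα value or the mean over their atoms).

## Solvation analyses

- **Shell counts**: a water or ethanol molecule is counted once when any of
  its atoms lies within the cutoff (default 5.0 Å; a 3–8 Å sweep is
  recommended because shell conclusions depend on it) of any site atom,
  under the minimum-image convention.
- **SASA**: Shrake–Rupley with a deterministic golden-spiral point set
  (default 960 points) on spheres of radius r_vdw + probe (probe 1.4 Å);
  areas split into hydrophilic (polar atoms: N/O/S and their hydrogens) and
  hydrophobic (carbon and its hydrogens) by the topology's polarity field.
  Occlusion is evaluated within the analysed subset, without periodic
  images.
- **Hydrogen bonds**: donor–acceptor distance ≤ 3.5 Å and D–H…A deviation
  from linearity ≤ 30°, hydrogens attached to donors by a ≤1.25 Å covalent
  criterion. Defaults are the common geometric choice; they are parameters,
  not claims.

vdW radii default to Bondi-style values (C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20, Na 2.27 Å …) and are overridable.

## Enzyme assay arithmetic

Activity from the indophenol assay is ΔOD₆₂₅ × n × k / t with t = 15 min by
default (one unit = 1 μmol NH₃/min). Michaelis–Menten fitting is nonlinear
least squares of v = V_max·S/(K_m+S) with V_max₀ = max(v) and K_m₀ = the
level nearest half-max (ties to the lower level); a fitted K_m outside
(0, 10·max S) is flagged unreliable. k_cat = V_max/(E) with min→s
conversion. Catalytic efficiency is reported as k_cat(s⁻¹)/K_m(mM), the
scale on which published parameter tables for this enzyme are numerically
self-consistent, with the strict per-molar value (×1000) also available;
k_cat values from such tables are consumed as printed because converting
V_max (μmol·min⁻¹·mg⁻¹) to a turnover requires the enzyme's molar mass.
Fold changes and relative activities are reported rounded to two decimals.

## Synthetic data: what it emulates, and what it does not

The generators are geometric and statistical, not physical, by design — the
estimators and screens are under test, never a force field:

- **Toy proteins** are backbone-only (N, CA, C, O) chains built by natural
  extension (NeRF) from ideal per-class dihedrals (helix −57°/−47°, sheet
  −139°/135°, loop −70°/150° with ±8° seeded jitter), centred in an
  orthorhombic box. The 392-residue toy hydrolase layout reproduces the six
  loop segments at 67-76, 82-107, 176-181, 254-261, 320-333 and 381-392; its
  sequence is a synthetic stand-in that pins the six experimentally mutated
  wild-type identities (H68, K70, A178, A321, S325, Q332).
- **Volume series** draw Gaussian volumes whose variance inverts the
  fluctuation relation for a target β_T (rejected if σ_V/⟨V⟩ > 0.2).
- **Breathing trajectories** scale a region's atoms isotropically about its
  centroid. Because the Voronoi boundary against fixed surroundings responds
  much more weakly than s³, the generator probes dV/ds numerically, builds a
  9-point calibration curve sized to cover ±5σ, and inverts it monotonically
  (PCHIP), so the realised volume series matches the drawn Gaussian to
  interpolation accuracy.
- **Solvated boxes** place 3-atom pseudo-water and 3-heavy-atom
  pseudo-ethanol by seeded rejection sampling with a 2 Å minimum separation;
  shell specs place exact molecule counts within a distance band of a site
  and keep all other molecules outside an exclusion radius, so shell counts
  are recoverable exactly.
- **Kinetics datasets** apply multiplicative Gaussian noise to an exact
  Michaelis–Menten curve over (0, 300] mM substrate levels.
- The synthetic per-region β_T response over the grid is
  β = base + amplitude·4x(1−x)·(0.2 + 0.8·p/p_max): strongest at
  intermediate ethanol (near-pure ethanol suppresses the response) and
  increasing with pressure, so a region's grid spread ≈ its amplitude.

Passing tests on these fixtures demonstrates the correctness of the
estimators, geometry and screening logic. They say nothing about real
solvent structure, force-field accuracy, or whether a real trajectory's β_T
spread identifies truly destabilised regions — those claims need real MD.

## Default study conditions and problem sizes

The default grid is 3 pressures (1, 500, 1000 bar) × 3 ethanol fractions
(10 %, 50 %, 100 % v/v) at 313 K, five parallels of 30 ns sampled at 1 ns —
45 runs, 1350 ns. The test and acceptance workloads scale the geometry
down: breathing-trajectory recovery runs a 14–22-residue protein in
~300 pseudo-waters for 100–150 frames (sampling-limited tolerances set by
√(2/n)); estimator recovery at n = 10⁴ uses the statistical series
generator; Monte-Carlo cross-checks of the tessellation use ≤20 sites and
4×10⁶ sample points; the noisy kinetics study uses 200 seeds at 5 % CV.

## Known limitations

- Orthorhombic boxes only; triclinic input is rejected explicitly.
- The dihedral heuristic is three-state and window-based; irregular real
  secondary structure should come from an external assignment file.
- SASA ignores periodic images (appropriate for a whole molecule in a
  sufficiently large box).
- Solvent counting assumes solvent residues are intact molecules with unique
  residue indices; a residue index spanning molecule classes is an error.
- The surrogate ΔΔG scorer is plumbing, not prediction.
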