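# Methods

This note documents the models implemented in `nanodna`, their
assumptions, the parameters that matter, and the limits of what the test
suite demonstrates.

## Target geometries

**Atomic model.** The high-resolution target is an idealized B-form double
helix: one base-pair template (an A–T pair with both sugar–phosphate
groups, 64 atoms) stacked `n_bp` times with a rigid +36° rotation about the
helix axis (+z) and a +0.34 nm translation per step.  Base pair 1 is
centred at z = rise/2 and indices increase with z.  Defaults reproduce the
canonical 41-BP / 82-nucleotide segment inside a bounding cylinder of
2.4 nm diameter; a 14.3 nm bounding height may be requested, and the
cylinder is always grown so that it contains every atomic volume (the
41 × 0.34 = 13.94 nm stack plus the overhang of the terminal phosphate
groups gives ≈14.37 nm in practice).

The template (`src/nanodna/data/bp_template.csv`, regenerated by
`scripts/make_data.py`) is built from idealized internal coordinates:
aromatic rings are regular polygons at 0.136–0.137 nm bond length, the
deoxyribose is a regular pentagon at 0.148 nm, and all exocyclic bonds use
standard mean lengths (C–C 0.152, C–O 0.143, P–O ester 0.160, phosphoryl
P–O 0.148, C–H 0.109 nm, …).  The companion bonds table documents every
covalent bond with its reference length; construction places atoms at
exactly those lengths, and the builder preserves them to numerical
precision (a rigid transform), which the test suite verifies.  The two
backbones are related by the base-pair dyad and are therefore antiparallel;
the phosphorus sits 0.96 nm from the axis.  The thymine methyl group is
modelled as individual C and H atoms.  The template is idealized, not
fibre-refined: torsion angles, sugar pucker and propeller twist are not
reproduced, and the base identity is fixed (A–T at every step).  Moiety
partition: the glycosidic C1′ and all primed/phosphate atoms belong to
`sugar_phosphate`; ring and exocyclic base atoms to `base`.

**Atom radii.** Target volumes are spheres with per-element radii
H 0.120, C 0.170, N 0.150, O 0.140, P 0.190 nm.  A point inside several
overlapping atoms is attributed to the atom with the smallest
distance-to-centre; remaining ties go to the lower base-pair index, then
the labeled strand.  Points inside the bounding cylinder but outside every
atom are tallied separately as *physical-indirect* hits and attributed to
the nearest moiety (the alternative — attributing to the base-pair slab
only — is not implemented).

**Simple model.** The semi-cylindrical model represents each nucleotide's
backbone as a 180° half-annulus (inner radius 0.5 nm, outer 1.15 nm,
thickness one rise), the two strands offset by 180° and each advancing by
the twist per base pair.  Bases are not represented and the chemistry
stage does not apply; the model exists to quantify what a coarse target
plus a higher threshold (below) can and cannot capture.

**PDB input.** Standard PDB ATOM/HETATM records are read through
Biopython, with Å→nm conversion at the reader boundary only.  DNA residues
map to moieties by atom-name convention (primed names and P/OP* are
backbone, the rest base); chains map to strands in order of appearance.
Atoms with elements outside the radius table are skipped with a counted
warning.

## Decay source

Spectra are line tables (energy in eV, electrons per decay) supplied as
CSV; no physical nuclide spectrum is bundled or asserted as correct, since
emission tables differ between nuclear-data libraries.  Sampling modes:
`poisson_lines` (default) draws an independent Poisson count per line —
atomic-relaxation correlations within a cascade are deliberately not
modelled — and `fixed_cascade` emits ⌊yield⌋ (+1 with the fractional
probability) electrons for deterministic tests.  Emission is isotropic.
Photons are outside the damage model.

Placement: `at_bp` puts the source at the labeled-strand sugar–phosphate
centroid of a base pair (covalent labeling; bp 21 by default, the centre
of the 41-mer), `at_distance` at a radial stand-off from the
bounding-cylinder surface at mid-height.  Per-BP profiles are reported
against rel_bp = bp − source_bp.

## Electron transport

The engine is an explicitly simplified event-by-event transport in
infinite homogeneous liquid water (1 g/cm³; the DNA volumes do not perturb
transport).  Per step: exponential free flight with mean
1/(n·σ_tot), channel choice proportional to the channel cross sections,
then

* **elastic** — direction change only, screened-Rutherford polar law with
  screening η = 16.5/E[eV];
* **ionization** — single effective binding energy B = 13 eV deposited at
  the site; secondary energy W drawn from f(W) ∝ 1/(W+B)² on
  [0, (E−B)/2]; the secondary is transported with an isotropic initial
  direction and inherits the primary's track id;
* **excitation** — a fixed 8 eV deposited locally;
* below the 10 eV cutoff the electron deposits its remaining energy
  locally (`subcutoff_absorption`).  The cutoff expresses the production
  cut as an energy rather than a range — the engine has no range tables.

The packaged tables (`xs_water.csv`) use a BEB-shaped ionization and
excitation cross section and a screened-Rutherford elastic cross section
with Z_eff = 7.42; magnitudes are within a factor ~2 of measured water
cross sections across 10 eV–10 keV, which is adequate for exercising the
damage-scoring chain but **not** a substitute for dielectric-response
track-structure physics.  Users with better tables can swap the CSV; whole
event streams from external codes can be imported through the documented
CSV/HDF5 layout.  Internal consistency is tested: energy conservation per
primary to 1e-6, exponential flight lengths, and agreement of the mean
primary path length with the CSDA-style integral of the same tables'
stopping power to 20%.

## Radiolysis chemistry

Species (·OH, H·, H₂O₂) are created at deposition sites at 1 ps with
per-event-kind branching yields.  Defaults — one ·OH per ionization, 0.3
per excitation, 0.1 H· and 0.05 H₂O₂ per ionization — are configuration
placeholders chosen to give a radical-rich environment, not measured
G-values, and are clearly surfaced in the run manifest.  Diffusion
coefficients: ·OH 2.8, H· 7.0, H₂O₂ 2.3 nm²/ns.

Brownian dynamics runs on a geometric schedule of 100 log-spaced intervals
from 1 ps to 1 µs (fine steps while the radical is near its birth place,
coarser later).  After every step — and once at birth — a species within
the reaction radius of a matching moiety reacts and is removed; among
simultaneous matches the smallest centre distance wins.  The ·OH radii are
the standard per-moiety values (Sugar 0.108 nm, bases 0.366–0.553 nm).
H· radii are not separately established; they reuse the ·OH radii times a
configurable factor (default 1.0) and the substitution is flagged at
runtime.  H₂O₂ has no channel and never reacts.  This step-by-step scheme
replaces the independent-reaction-times (IRT) algorithm used by full
radiation-chemistry codes: it is simpler and directly testable, at the
cost of possible step-overshoot (a walker can jump across a thin reaction
shell within one step, so very thin shells are undersampled at late, long
steps) and no radical–radical recombination or homogeneous chemistry
network (e⁻aq, H₃O⁺, OH⁻ are absent).  Scavenging is an on/off switch:
disabling the stage emulates a DMSO environment and forces the chemical
yields to exactly zero.

## Damage scoring

* Physical break: accumulated direct energy in one sugar–phosphate
  moiety ≥ 10 eV within a decay.  The comparison is inclusive (≥); strict
  vs inclusive is unobservable at float resolution.  Accumulation is per
  moiety per decay because dense Auger cascades routinely split their
  energy over several sub-threshold depositions; a `per_event` mode
  preserves the single-hit alternative.
* Chemical break: ≥ 1 Sugar-channel reaction at the moiety.  Base-channel
  reactions are tallied but never converted into strand breaks (nucleobase
  damage chemistry is out of scope).
* At most one break per (moiety, mechanism) per decay.
* Simple model: per-segment accumulated energy ≥ 17.5 eV, standing in for
  physical *and* chemical action in one threshold.
* DSB pairing: exact maximum-cardinality matching between opposite-strand
  breaks within d_DSB base pairs (default 10; 3 and 5 supported), then
  minimum total separation, then the lexicographically lowest pairing (by
  base-pair indices and mechanisms).  The exact search is affordable
  because a single decay produces few breaks; the classifier is verified
  against an independent exhaustive-enumeration oracle.  Unpaired breaks
  are the residual SSBs, so reported SSB yields exclude breaks consumed by
  DSBs — this matches the observed opposite SSB/DSB trends when d_DSB
  shrinks.
* Categories: both physical sharing a primary track id →
  correlated-physical (a single track cutting both strands); otherwise
  physical+physical, physical+chemical, or chemical+chemical.

Tallies accumulate per-decay means of all yields, per-BP energy profiles
split by strand, moiety and direct/physical-indirect mechanism, per-BP SSB
probabilities, and the energy entering the bounding cylinder.  The
decomposition report rounds percentages half-away-from-zero to integers.

## Numerical and design choices

* All randomness flows from one integer seed through
  `numpy.random.SeedSequence.spawn`, one child generator per decay; runs
  are bitwise reproducible and decays are independent.
* Internal units: nm, eV, s (diffusion in nm²/ns); Å only at the PDB
  boundary.
* Chemistry walkers are culled from proximity checks (not from diffusion)
  while outside the bounding cylinder plus the largest reaction radius —
  an exact optimization, since no reaction is possible there.
* Degenerate inputs: empty spectra, zero-decay scenarios, empty event
  lists and empty PDB files all return well-formed empty results; invalid
  configuration (unknown keys, missing files, non-positive radii or
  thresholds, out-of-range base pairs, energies above the table range)
  fails fast with a named error.

## Problem sizes used in the checks

The end-to-end acceptance study uses 10³ decays of a synthetic three-line
spectrum (100 eV × 3.0, 500 eV × 2.0, 2000 eV × 0.5 electrons/decay —
a ~2.3 keV/decay Auger-like cascade) at 1 nm and 5 nm stand-off; property
checks use 10³ random break sets (≤ 12 breaks), 10³ random points for the
hit-location oracle, 10⁴ Brownian walkers, and 100-decay scenarios for
reproducibility.  These sizes give stable Monte Carlo statistics at desk
scale; yields at 10³ decays carry a few-percent statistical error.

## What passing tests do and do not show

The synthetic fixtures exercise every stage against analytic expectations
(Poisson/binomial moments, the Einstein relation, exponential flight
lengths, conservation laws, exhaustive oracles).  They demonstrate that
the bookkeeping — geometry addressing, mechanism attribution, DSB
taxonomy, scavenger behaviour, distance trends — is correct.  They do not
validate the absolute magnitude of simulated yields for real nuclides:
those depend on the simplified cross sections, the placeholder branching
yields, and the idealized template, and should be calibrated against a
full track-structure code or experiment before quantitative use.
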