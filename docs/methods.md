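# Methods

## The model

`cycshell` treats a virus-like shell of cationic cyclic d,l-octapeptides as
a geometry-and-labels problem. Every statistic it computes — densities,
hydrogen-bond censuses, contact counts, coordination numbers, radii of
gyration — is a function of atom positions, periodic box lengths, and
per-atom labels (species, residue, role, peptide identity). No force field,
energetics, or dynamics enter anywhere: the package builds initial
configurations and analyzes trajectories produced elsewhere.

### Shell construction

The preassembled shell is built from tessellation units of
`peptides_per_unit` (default 3) stacked cyclopeptide rings:

* Unit directions come from a golden-angle (Fibonacci) lattice, which is
  deterministic and near-uniform: for n ≥ 50 the nearest-neighbor angular
  spacing stays within 20% of the uniform ideal 2·√(π/n) with a
  coefficient of variation below 0.15.
* Each unit stacks its rings coaxially along the radial direction at
  `stack_spacing` (default 4.85 Å, the axial repeat of cyclic d,l-peptide
  stacks), centered so the middle ring sits exactly at `shell_radius`
  (default 45 Å). The mean radial distance of unit centers therefore equals
  the shell radius to machine precision, and the unit-center point set
  satisfies the thin-shell identity R_g = shell_radius.
* The azimuthal orientation of each unit is drawn from the seeded
  generator; the initial register relaxes immediately in any real
  trajectory, so no particular orientation is preferred.

The cyclopeptide template is idealized: a planar octagonal Cα ring of
radius `ring_radius` (default 4.1 Å) with, per residue, an amide N–H and a
carbonyl O alternating above/below the plane with residue parity (the
hydrogen-bonding register of d,l-alternating rings), and one side-chain
pseudo-group. Side-chain groups are deliberately compact: the heavy site
sits only 0.2 Å outside the Cα ring, azimuthally between Cαs, and donor
hydrogens tilt mostly out of plane (in-plane component 0.2). At the default
144-unit, 45 Å packing, adjacent inner rings are only ~10.3 Å apart, so any
template whose atoms reach beyond ~4.7 Å in-plane would collide with
neighboring units; the compact pseudo-group keeps the default build
clash-free (minimum inter-unit atom distance ≈ 1.8 Å) while preserving
everything the analyses consume: donor/acceptor sites with explicit
hydrogens, heavy-atom contact geometry, and labels. An all-atom template
can be substituted by extending the residue mapping table. Builds abort
with an error if atoms of different units approach below 1 Å.

Residue chirality is never used: DLE differs from LEU only by name, since
every statistic here is geometric.

### Counterion placement

`place_counterions` resolves `count="auto"` to |total peptide charge| /
|valence| (a non-integer quotient is an error — there are no fractional
ions) and rejection-samples uniform positions and orientations so that no
ion atom comes within `min_separation` (default 3.5 Å, minimum image) of
any existing atom, including previously placed ions. Polyatomic phosphates
are tetrahedral with P–O 1.54 Å; the P atom is the reference atom for
density profiles. Placement is deterministic under the seed and exhausts a
documented attempt budget before failing with the achieved count.

## Analyses

**Coordinates are kept unwrapped**; the minimum-image convention is applied
only inside distance computations. This avoids double-wrapping artifacts in
centers of mass and radii of gyration for an assembly that may span the
box. Neighbor searches use periodic KD-trees; the test suite holds them to
exact set equality against all-pairs oracles.

* **ρ_norm(r)** histograms distances of selected atoms from the reference
  selection's center of mass (mass-weighted by default; per frame), divides
  by the particle count N and the exact spherical-shell volume
  (4/3)π(r₂³−r₁³), and averages over frames. Distances to the COM are
  computed without imaging, since minimum imaging against a COM is
  ill-defined for box-spanning assemblies. The normalization identity
  Σ ρ_norm·V_shell = 1 holds to 1e−9 whenever all particles are binned.
  Default bin width 1 Å, which resolves the 10–20 Å shell features of
  interest.
* **Hollow classification** declares a shell hollow when the mean number
  density inside some radius ≥ `inner_radius_min` (default 10 Å) stays
  below `zero_tol` (default 0.5%) of the species' mean density over its
  occupied radial extent. The tolerance is density-relative rather than a
  fraction of total particles: a small central sphere holds a small
  fraction of even a *uniform* distribution, so a fraction-of-total rule
  would misclassify any dilute dispersed system in a large box as hollow.
* **Hydrogen bonds**: heavy–heavy distance ≤ 3.0 Å (inclusive) and
  donor–hydrogen–acceptor angle at the hydrogen ≥ 150° (inclusive), donor
  and acceptor in different residues. Each hydrogen of a multi-hydrogen
  donor may carry its own bond — guanidinium multidentacity requires
  per-hydrogen accounting. Hydrogens must be explicit in the input; none
  are inferred.
* **Condensation** uses heavy atoms only (hydrogens would make a 3 Å rule
  trivially satisfiable): an anion is condensed when any heavy atom is
  within 3 Å of any peptide heavy atom; each condensed ion is attributed to
  its nearest peptide, ties broken by lowest peptide id. *Bridging* anions
  form hydrogen bonds with Arg/Gln side chains of ≥ 2 distinct peptides;
  ratios are reported against total and against condensed anions (null
  when nothing is condensed).
* **Hydration**: g(r) is the standard pair correlation with bulk density
  N_targets/V_box; the first minimum is located on a 3-bin moving average
  (smoothing is for detection only — raw g(r) is what is reported) and an
  absent minimum is an error, never a guess. Coordination numbers come from
  direct counting within the first minimum, not the quadrature
  ∫4πr²ρg dr, avoiding bias at coarse bins. Water is identified by its
  oxygen throughout. Waters-per-peptide uses a 3.5 Å first-shell cutoff by
  default; this cutoff is a convention, prominently configurable.
* **R_g plateau**: the earliest frame from which every sliding-window
  least-squares slope stays below `slope_tol` (default 0.01 Å/frame,
  window 20% of the series). Simple, seedless, reproducible. R_g defaults
  to mass-weighted peptide atoms only, matching the shell-size reading.
* **Debye length** κ⁻¹ = √(ε₀ε_r k_B T / 2 N_A e² I_c) with ionic strength
  I_c = ½Σc_i z_i² converted to number density; ε_r defaults to 78.4
  (water, 298 K). The I⁻¹ᐟ² scaling is exact and tested.

## Synthetic fixtures and what they establish

The generators in `cycshell.synth` plant configurations whose statistics
are known by construction, and emit that truth separately — it is never
recomputed from the fixture. Hydrogen-bond geometry is planted with margins
of ≥ 0.05 Å and ≥ 5° from the 3 Å / 150° thresholds so that
boundary-inclusiveness conventions cannot flip a truth label, and planted
groups are separated by > 6 Å so no accidental cross-group bonds arise.

These fixtures emulate the *geometry* of shells, hydrogen-bond networks,
bridging ions, and hydration shells — not their physics. Passing tests
demonstrate that the detectors count exactly what is present under the
stated criteria (including under periodic boundaries, rotations, and
translations, and in frame-by-frame agreement with brute-force oracles on
jittered trajectories); they do not validate force fields, sampling, or any
claim about what real trajectories contain. Note that under per-atom
Gaussian jitter of σ = 0.1 Å, distance and angle fluctuations (~0.14 Å,
~8°) exceed the planted margins, so per-frame counts on jittered fixtures
legitimately fluctuate below the planted count; the tests freeze the
observed band from an oracle run at a fixed seed rather than assuming
near-perfect survival.

## Numerical choices

* Thresholds are inclusive (≤ distance cutoffs, ≥ angle cutoff); fixture
  margins make this choice unobservable in tests.
* Minimum-image displacement components lie in [−L/2, L/2).
* 0-based contiguous atom ids internally; PDB serials are labels only.
* Report CSVs print floats with `%.6g` and contain no timestamps, making
  reruns byte-identical; the manifest embeds the config hash.
* Problem sizes in tests (≤ 5,000-atom oracle fixtures, 432-peptide builds,
  a few thousand fixture points) keep the whole suite to seconds while
  leaving every detector's exactness checked against an independent oracle.

## Known limitations

* The cyclopeptide template is a reduced representation; absolute
  backbone-census values depend on its idealized geometry (the stacking
  register is faithful, the side-chain reach is not).
* XYZ files carry no residue structure, so only single-atom residues
  round-trip through that format; multi-frame binary formats are out of
  scope (convert externally to multi-model PDB).
* The hollow classifier assumes a roughly isotropic occupied extent; highly
  anisotropic aggregates would need a tailored reference density.
* `waters_per_peptide` values depend strongly on the first-shell cutoff
  convention; compare like with like.
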