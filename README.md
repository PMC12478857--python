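# cycshell

Build and analyze counterion-stabilized cyclopeptide virus-like shells.

Synthetic virus-like particles (VLPs) can be assembled from cationic cyclic
d,l-octapeptides (sequence cyc-Gln-DLeu-Arg-DLeu-Arg-DLeu-Arg-DLeu, formal
charge +3). Whether such a highly charged shell holds together depends on the
counterions around it: polyatomic anions such as H2PO4⁻ and PO4³⁻ condense on
the shell, neutralize the Coulomb repulsion between peptides, and bridge
peptides through multidentate hydrogen bonds with arginine side chains, while
monatomic anions (F⁻, Cl⁻) coordinate too weakly to hold the assembly
together. `cycshell` is a toolkit for people studying this class of systems
with molecular simulation: it constructs the preassembled shell with
neutralizing counterions, and computes the trajectory statistics that
diagnose shell stability.

## What it computes

* **Shell construction** — tessellation units of three stacked idealized
  cyclopeptide rings, distributed near-uniformly on a sphere (Fibonacci
  lattice, default 144 units = 432 peptides, radius 45 Å) with ring normals
  pointing radially; counterions placed at random with exact charge
  neutralization (`count="auto"`).
* **Normalized radial density** ρ_norm(r): the radial number density of a
  species about its center of mass divided by its particle count N, so
  ρ_norm(r)·N is the local number density. A vanishing ρ_norm between the
  center and a finite radius diagnoses a hollow shell.
* **Hydrogen bonds** — donor–H–acceptor triples with heavy-atom distance
  ≤ 3 Å and D–H–A angle ≥ 150°; per-anion bond distributions and the
  fraction donated by each residue type.
* **Bridging and condensation** — an anion is *condensed* when any heavy
  atom is within 3 Å of a peptide heavy atom, and *bridging* when it forms
  hydrogen bonds with Arg/Gln side chains of ≥ 2 distinct peptides; both
  bridging ratios (per total and per condensed anion) are reported.
* **Hydration** — pair correlation g(r), its first minimum, and first-shell
  coordination numbers by direct counting; waters per peptide.
* **Convergence and screening** — radius of gyration
  R_g = √(Σ w_i |r_i − r_com|² / Σ w_i) with sliding-window plateau
  detection, and the Debye length κ⁻¹ = √(ε₀ε_r k_B T / 2 N_A e² I_c).

A synthetic-fixture module generates systems with planted, exactly known
ground truth (hollow shells, dispersed gases, hydrogen-bond triples with
controlled geometry, bridging anions, hydration shells, jittered
trajectories); every statistic in the pipeline is validated against those
truths and against brute-force oracles.

## Worked example

```python
import cycshell as cs

shell = cs.build_shell()                      # default: 432 peptides on a 45 Å sphere
print("peptides:", shell.topology.peptide_id.max() + 1)
print("peptide charge:", cs.peptide_formal_charge(shell.topology))

system = cs.place_counterions(shell, cs.IonSpec("H2P", valence=-1), seed=1)
n_ions = len({a.residue_index for a in system.topology if a.species == "anion"})
print("H2PO4- placed:", n_ions)

profile = cs.radial_density(system, "species=peptide and role=reference_atom",
                            "species=peptide")
hollow, inner = cs.classify_hollow(profile)
print(f"hollow shell: {hollow} (empty out to {inner:.0f} Å)")

rg = cs.radius_of_gyration(system)
print(f"radius of gyration: {rg:.1f} Å")

print(f"Debye length, 1 M NaCl: {cs.debye_length(cs.nacl_species(1.0)):.2f} Å")
```

prints

```
peptides: 432
peptide charge: 1296
H2PO4- placed: 1296
hollow shell: True (empty out to 40 Å)
radius of gyration: 45.4 Å
Debye length, 1 M NaCl: 3.04 Å
```

The shell carries 432 × (+3) = +1296 charge, so auto-neutralization places
exactly 1296 monovalent anions (432 for a trivalent anion). The freshly
built shell is hollow — the peptide reference-atom density is zero from the
center out to ~40 Å — and its radius of gyration sits at the construction
radius; in a relaxed trajectory the plateau of this series marks
convergence. The 1 M NaCl Debye length of ~3 Å explains why excess salt
screens interpeptide repulsion without disturbing sub-3 Å contacts.

## Command line

Every analysis is also a `cycshell` subcommand over PDB/XYZ inputs
(`build-shell`, `make-fixture`, `density`, `hbonds`, `bridges`, `condense`,
`contacts`, `hydration`, `rg`, `debye`, `report`). `cycshell report --config
run.yaml` chains all applicable stages into table-shaped CSVs plus a
manifest that echoes every cutoff; reruns are byte-identical. Exit codes:
0 success, 2 configuration error, 3 analysis error.

### Selection grammar

Selections are conjunctions of `key=value` clauses joined by ` and `, where
a value list `a,b` means "either": e.g.
`"species=peptide and role=reference_atom"`, `"resname=ARG,GLN"`. Keys:
`species`, `resname`/`residue_name`, `role`, `name`, `element`,
`peptide_id`, `residue_index`.

### File formats

PDB (`ATOM`/`HETATM`, `CRYST1` box, `MODEL`/`ENDMDL` trajectories, `TER`
delimiting peptides) and XYZ point clouds with a `box Lx Ly Lz` comment
line. Species and roles are inferred from residue names through an editable
mapping table (`src/cycshell/data/residues.yaml`) covering ARG, LYS, GLN,
LEU/DLE, HOH/TIP3, H2P, PO4, CL, F, NA and the synthetic-fixture residues.

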