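# Residue-name -> species / role / charge mapping table.
#
# This table is the single source of truth for how residue names found in
# structure files are labeled.  Edit or extend it to support new residue
# dialects; the analyses only ever consult the labels, never the names.
#
# Per atom:
#   element    chemical element (for masses and heavy-atom tests)
#   roles      any of: backbone, sidechain, donor_heavy, acceptor_heavy,
#              hydrogen, reference_atom
#   hydrogens  names (same residue) of hydrogens bonded to a donor heavy atom
#
# Peptide residues use a reduced side-chain representation: one heavy-atom
# pseudo-group per side chain, with explicit hydrogens on donor sites.

ARG:
  species: peptide
  charge: 1
  atoms:
    N:   {element: N, roles: [backbone, donor_heavy], hydrogens: [HN]}
    HN:  {element: H, roles: [backbone, hydrogen]}
    CA:  {element: C, roles: [backbone]}
    O:   {element: O, roles: [backbone, acceptor_heavy]}
    CZ:  {element: C, roles: [sidechain, donor_heavy], hydrogens: [HS1, HS2, HS3, HS4]}
    HS1: {element: H, roles: [sidechain, hydrogen]}
    HS2: {element: H, roles: [sidechain, hydrogen]}
    HS3: {element: H, roles: [sidechain, hydrogen]}
    HS4: {element: H, roles: [sidechain, hydrogen]}

LYS:
  species: peptide
  charge: 1
  atoms:
    N:   {element: N, roles: [backbone, donor_heavy], hydrogens: [HN]}
    HN:  {element: H, roles: [backbone, hydrogen]}
    CA:  {element: C, roles: [backbone]}
    O:   {element: O, roles: [backbone, acceptor_heavy]}
    NZ:  {element: N, roles: [sidechain, donor_heavy], hydrogens: [HS1, HS2, HS3]}
    HS1: {element: H, roles: [sidechain, hydrogen]}
    HS2: {element: H, roles: [sidechain, hydrogen]}
    HS3: {element: H, roles: [sidechain, hydrogen]}

GLN:
  species: peptide
  charge: 0
  atoms:
    N:    {element: N, roles: [backbone, donor_heavy], hydrogens: [HN]}
    HN:   {element: H, roles: [backbone, hydrogen]}
    # The Gln Calpha is the per-peptide reference atom for density profiles.
    CA:   {element: C, roles: [backbone, reference_atom]}
    O:    {element: O, roles: [backbone, acceptor_heavy]}
    OE1:  {element: O, roles: [sidechain, acceptor_heavy]}
    NE2:  {element: N, roles: [sidechain, donor_heavy], hydrogens: [HE21, HE22]}
    HE21: {element: H, roles: [sidechain, hydrogen]}
    HE22: {element: H, roles: [sidechain, hydrogen]}

# d-leucine: chirality is irrelevant to the geometric statistics computed
# here, so DLE differs from LEU only by name.
DLE: &leu
  species: peptide
  charge: 0
  atoms:
    N:   {element: N, roles: [backbone, donor_heavy], hydrogens: [HN]}
    HN:  {element: H, roles: [backbone, hydrogen]}
    CA:  {element: C, roles: [backbone]}
    O:   {element: O, roles: [backbone, acceptor_heavy]}
    CG:  {element: C, roles: [sidechain]}

LEU: *leu

HOH: &water
  species: water
  charge: 0
  atoms:
    O:  {element: O, roles: [acceptor_heavy, donor_heavy], hydrogens: [H1, H2]}
    H1: {element: H, roles: [hydrogen]}
    H2: {element: H, roles: [hydrogen]}

TIP3: *water

# Dihydrogen phosphate; P is the reference atom for polyatomic anions.
H2P:
  species: anion
  charge: -1
  atoms:
    P:   {element: P, roles: [reference_atom]}
    O1:  {element: O, roles: [acceptor_heavy, donor_heavy], hydrogens: [HO1]}
    O2:  {element: O, roles: [acceptor_heavy, donor_heavy], hydrogens: [HO2]}
    O3:  {element: O, roles: [acceptor_heavy]}
    O4:  {element: O, roles: [acceptor_heavy]}
    HO1: {element: H, roles: [hydrogen]}
    HO2: {element: H, roles: [hydrogen]}

PO4:
  species: anion
  charge: -3
  atoms:
    P:  {element: P, roles: [reference_atom]}
    O1: {element: O, roles: [acceptor_heavy]}
    O2: {element: O, roles: [acceptor_heavy]}
    O3: {element: O, roles: [acceptor_heavy]}
    O4: {element: O, roles: [acceptor_heavy]}

CL:
  species: anion
  charge: -1
  atoms:
    CL: {element: CL, roles: [acceptor_heavy, reference_atom]}

F:
  species: anion
  charge: -1
  atoms:
    F: {element: F, roles: [acceptor_heavy, reference_atom]}

NA:
  species: cation
  charge: 1
  atoms:
    NA: {element: NA, roles: [reference_atom]}

# --- synthetic-fixture residues (planted-truth test beds) -------------------

# Minimal donor group: one heavy donor site with one explicit hydrogen.
DON:
  species: peptide
  charge: 0
  atoms:
    D:  {element: N, roles: [sidechain, donor_heavy], hydrogens: [HD]}
    HD: {element: H, roles: [sidechain, hydrogen]}

# Minimal acceptor site.
ACC:
  species: anion
  charge: 0
  atoms:
    A: {element: O, roles: [acceptor_heavy, reference_atom]}

# Shell pseudo-atom (hollow-shell density fixtures); one atom per peptide.
SHP:
  species: peptide
  charge: 0
  atoms:
    PS: {element: C, roles: [reference_atom]}

# Dispersed-gas pseudo-atom (uniform-gas density fixtures).
GAS:
  species: peptide
  charge: 0
  atoms:
    GS: {element: C, roles: [reference_atom]}
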