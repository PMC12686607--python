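# Methods

## Model

The package computes per-residue protein–ligand interaction energies with
the conjugated-caps fragmentation scheme. For residue R_i of a chain, the
caps C_{i-1} and C_{i+1} are the *entire* covalently adjacent residues (not
just their backbone units); the two outer peptide bonds — between C_{i-1}
and residue i−2, and between C_{i+1} and residue i+2 — are cut and each
dangling valence is saturated by a hydrogen placed on the former bond
vector at a standard length (N–H 1.01 Å, C–H 1.09 Å). Chain termini give
single-sided caps that keep their real terminal groups (ammonium /
carboxylate as prepared). The interaction energy is the four-term
combination

    E(L−R_i) = E(L·C R C) − E(L·C C) − E(C R C) + E(C C),

negative attractive, positive repulsive, kcal/mol throughout. Removing R_i
for the caps-only terms exposes the two inner peptide bonds, saturated by
the same rule. Crystallographic waters attached to R_i appear exactly when
R_i does.

**Assumptions.** Structures arrive prepared: heavy atoms complete,
protonation resolvable by fixed pH-7.4 rules, geometry already optimised
upstream. Fragmentation assumes an unbroken chain (peptide C–N ≤ 2.0 Å;
violations raise a chain-discontinuity error). Disulfide bridges are not
cut specially, and covalent ligands are out of scope.

## Water attachment

A water is assigned to at most one pocket residue: the one with the
smallest donor–acceptor heavy-atom distance (water O against residue N/O)
among residues within the cutoff. The criterion is distance-only — no
angular term — because that keeps the rule reproducible with a single
tunable knob; `hbond_dmax` defaults to 3.5 Å, the conventional
donor–acceptor heavy-atom limit. Waters attach to R_i rather than to its
caps; for any pairwise-additive backend an attachment to the caps would
cancel out of the four-term combination anyway, so this convention changes
nothing classically and fixes the QM fragment contents deterministically.

## Pocket shells and convergence

Residues enter the pocket when any atom (hydrogens included by default;
`atom_mode="heavy_atoms"` available) lies within r of any ligand atom,
closed boundary, so membership is monotone in r. The radius grid is
r = n/2 starting at 0.5 Å — early shells are usually empty, which costs
nothing. The cumulative total binding energy E(r) is declared converged at
the first grid radius r_k with |E_{k+1} − E_k| / |E_{k+1}| < threshold
(default 0.10) and E_{k+1} ≠ 0. The denominator is the *newer* total; near
convergence the alternative (older total) differs negligibly, and the
convention is recorded on every profile. The ratio is scale-free, so
convergence detection is invariant under uniform energy rescaling.

## Energy backends

**Classical pairwise.** E = Σ_pairs [332.0637·q_a·q_b/(ε·d) +
4ε_LJ((σ/d)¹² − (σ/d)⁶)] with Lorentz–Berthelot combining. The uniform
dielectric ε divides the Coulomb term — a deliberately crude continuum
stand-in for CPCM that preserves the properties the algebra needs: strict
pairwise additivity and exact 1/ε scaling. ε defaults to 40 (the value
commonly found to describe protein–ligand interfaces well); 10 and 40 are
both evaluated in a standard run, with ranking at ε = 40. The embedded
parameter set is minimal: CHARMM-like backbone charges, TIP3P water,
element-based side-chain/ligand fallbacks, element-keyed LJ. Per-residue
charges are shifted uniformly so they sum exactly to the residue's formal
charge, which keeps monopole bookkeeping exact. External tables are
accepted as TSV (residue, atom_name, charge, sigma, epsilon). The energy
zero of a fragment is arbitrary; only the four-term difference is
meaningful, so no zero is configurable.

**Saturating cap hydrogens are spectators in the classical backend** (zero
charge, zero LJ). They exist to satisfy valence in a quantum calculation;
giving them classical parameters would let the two extra hydrogens of the
caps-only terms interact with the ligand and spoil the exact collapse of
the four-term combination onto the direct ligand↔residue sum. With inert
cap hydrogens the collapse is exact to round-off, which is what the oracle
tests assert at 1e-8 kcal/mol. QM decks write them as real hydrogens.

**QM decks.** `write_qm_deck` emits a Gaussian-style single point: route
line with the functional and basis labels (defaults B97D, 6-311+G(d,p) —
the dispersion-corrected GGA setup typical for this analysis), an
implicit-solvent keyword (CPCM) whose dielectric is passed through the Read
block (`eps=…`), then charge/multiplicity and Cartesian coordinates.
`parse_qm_energy` converts the *last* "SCF Done" energy at
627.509474 kcal/mol per hartree and refuses non-converged logs. No
counterpoise/BSSE correction is applied to the four terms.

## Synthetic data

The generator produces the class of inputs the pipeline assumes, not
crystallographic realism: an extended β-strand peptide (φ = −135°,
ψ = 135°, idealised bond lengths/angles), default 8 residues of poly-ALA
with ASP at position 3 and LYS at position 7 so both charge signs are
exercised; a rigid polar 13-atom ligand (an N-methyl glycolamide template
with three labelled regions i/ii/iii) whose centroid sits 5.0 Å from the
anchor residue's CA along the backbone-plane normal, orientation drawn
from the seeded RNG until clash-free (all-atom contact ≥ 1.7 Å); waters
2.85 Å from the backbone carbonyl oxygens of residues 2 and 4 — inside
H-bond range and nearest to their targets by construction. Positional
jitter and ligand charge noise are 0 by default and are turned on by the
property tests. The seed fixes everything; equal specs give byte-identical
PDB output.

What a green test on this world establishes: the fragment bookkeeping,
charge accounting, water attachment, shell selection and the four-term
algebra are exact for additive energetics. What it does not establish:
anything about DFT-level energetics, polarisation, charge transfer or
dispersion beyond LJ — those enter only through the external-engine path —
nor robustness to crystallographic pathologies (gaps, alternate chains,
unusual residues) beyond what the error contracts cover.

## Numerical choices

- Coulomb constant 332.0637 kcal·Å/(mol·e²); 1 hartree = 627.509474 kcal/mol.
- Shell boundary closed (d ≤ r); contact-annotation ties broken by the
  lower ligand atom index; water-assignment ties by pocket order.
- Altloc resolution: highest occupancy, ties to label A (also available:
  always label A). Resolution never yields duplicate atom names.
- Hydrogen placement uses idealised local geometry; the lone-substituent
  direction on a centre with three neighbours is taken along the
  neighbour-triangle normal, which stays stable where the naive negated
  bond-vector sum degenerates.
- Atom pairs closer than 0.5 Å trigger a clash warning but still evaluate.
- A pocket run tolerates per-residue failures up to a 10% budget (so a few
  unparameterisable residues do not kill a run), then aborts with the
  collected reasons.

## Known limitations

- pKa prediction is out of scope: only the fixed pH-7.4 rule set is
  implemented (ASP/GLU −1, LYS/ARG +1, HIS neutral Nε tautomer unless
  overridden per residue, zwitterionic termini). Other pH values raise
  rather than guess.
- Missing side-chain heavy atoms are rejected unless a caller-supplied
  rebuild hook fills them; no reconstruction method is bundled.
- Metal ions are retained in the structure with their nominal charges but
  excluded from the residue decomposition (no caps are defined for them).
- The classical backend's long-range tails are real 1/d² monopole–dipole
  electrostatics: a charged residue still sees a few 1e-3 kcal/mol from a
  polar ligand at 50 Å. This is physics, not fragmentation error — the
  four-term result agrees with the direct pairwise sum to better than
  1e-8 kcal/mol at every separation.
- Interaction-type labels (hydrogen bond, π-stacking, …) are not assigned;
  the package's claim is energies and geometric contacts, not bond-type
  taxonomy.
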