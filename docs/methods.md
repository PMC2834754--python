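# Methods

This note documents the models, estimators and conventions behind
`ppiface`, the parameters that matter, and what the synthetic test data
do and do not establish.

## Interface definition by buried surface area

The interface between partner sides *A* and *B* is defined through the
change in solvent-accessible surface area (SASA) on complexation:
ΔX = SASA(X alone) − SASA(X in complex), computed over heavy protein
atoms only. The per-complex "interface area" descriptor is the mean of
the two sides, (ΔA+ΔB)/2 — one-side-equivalent burial, the convention
under which the reference interfaces span ~240–950 Å² against ~1000 Å²
for typical transient heterodimers. Total two-sided burial would double
these numbers; the gap-volume index uses the two-sided sum (see below).

SASA uses a Shrake–Rupley estimator with a deterministic Fibonacci
sphere lattice (default 960 points/atom, probe 1.4 Å) and a Bondi-type
element radii table (C 1.70, N 1.55, O 1.52, S 1.80 Å; the set name is
recorded in every result for provenance). Determinism was preferred over
random point sets so that identical inputs give identical descriptors.
The lattice is not symmetric under reflection, so exactly mirror-
symmetric toy complexes show a small (≈4% at 960 points, ≈0.3% at 4000)
side imbalance; this is a discretization artifact, not a bug, and
vanishes with point count. Atoms are interface atoms when they lose
more than 0.1 Å² (a numerical-noise floor at 960 points; configurable);
residues with at least one such atom are interface residues.

Inhibitor coverage (H_ASA, %) is the interface-restricted burial ratio:
100 × (ΔASA of the protein–protein interface atoms caused by the bound
inhibitor) / (ΔASA of those same atoms caused by the protein partner),
with atoms mapped between the two crystal forms by chain, residue number
and atom name, clamped to [0, 100]. The published table gives no formula
for this column; the clamped interface-restricted ratio is consistent
with the printed values (e.g. 100.0 where the inhibitor covers the whole
interface region) but the denominator choice is this package's own.

## Shape descriptors

Planarity is the RMS perpendicular distance of the interface atoms to
their least-squares plane (principal-component fit of the centered
coordinates). Eccentricity is √(λ₂/λ₁) over the two in-plane
eigenvalues — a ratio of axis *lengths*, not variances; the published
0.42–0.89 range is compatible with either convention, so the choice is a
documented constant.

Gap volume is estimated on a regular grid (default 1.0 Å): a cell counts
when its center is (i) outside every atom's van der Waals sphere,
(ii) within 5.0 Å of a heavy atom of each partner, and (iii) *between*
the partners, operationalized as the nearest atoms of the two sides
lying on opposite sides of the point (negative dot product of the two
nearest-atom vectors). Without (iii) the rim around the contact patch
dominates the estimate and the parallel-plate closed form
S·(d − 2r_vdW) is missed by >50%; with it the estimator is within ~10%
on plate toys and converges under grid refinement. The gap-volume index
divides by the *two-sided* burial, GVi = GV/(ΔA+ΔB), the standard
tightness definition; a few rows of the bundled table are mutually
inconsistent under any single formula (notably the XIAP entries), so GVi
is always recomputed from GV and ΔASA, never copied. Note that the
"dilate by k ⇒ GV ~ k³, ΔASA ~ k²" intuition fails for a hard-sphere
model: uniform coordinate dilation with fixed atomic radii destroys the
SASA contact entirely once center distances exceed r₁+r₂+2·probe. The
meaningful scalings, which the tests check, are lateral patch growth
(GV and ΔASA both ~k², GVi stable) and separation widening (GVi rises).

## Contacts

Hydrogen bonds use a distance criterion between the *hydrogen* and the
acceptor (≤ 3.2 Å), so polar hydrogens are placed with ideal geometry
when the input lacks them: 1.0 Å N–H / 0.96 Å O–H; sp² donors from the
bisector (one heavy-neighbor frame for –NH₂ groups, two-neighbor
bisector for ring/backbone NH); rotatable hydroxyls and ammonium groups
oriented toward the candidate acceptor, accepted only when the
antecedent–donor–acceptor angle admits it (≥ 90°). Each donor hydrogen
contributes at most one bond (nearest acceptor), only cross-interface
pairs count, and a D–H···A ≥ 90° sanity filter (configurable off) stands
in for the manual inspection step of the original protocol. No further
angular term is applied — the criterion is deliberately distance-led.
Histidine ring nitrogens are treated as donor-or-acceptor, since the
protonation used in the original manual checks is unknowable. Hydrogen-
bond density is 100 × n_bonds / interface area (one-side-equivalent).

Salt bridges: minimum functional-atom distance (Asp OD1/OD2, Glu
OE1/OE2 vs Lys NZ, Arg NE/NH1/NH2, His ND1/NE2) strictly below 4.0 Å,
residues on opposite sides and both in the interface residue set; one
bridge per residue pair. His counts as basic, consistently with the
residue-class table (charged = Asp, Glu, Lys, Arg, His).

Interface segments: a segment is a stretch of residues starting and
ending with interface residues; two interface residues share a segment
iff separated by at most `max_gap` consecutive non-interface residues,
and only interface residues count toward segment length. The gap bound
is not quantified in the descriptor literature as printed; the default
of 4 follows the behavior of the interface-analysis servers this
package replaces and is exposed as a parameter. The class rule is
class I ⇔ fewer than six segments summed over both partners' chains.

Secondary structure is assigned by a self-contained dihedral-window
scheme (helix: φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]; strand:
φ ∈ [−180°, −45°], ψ ≥ 80° or ≤ −160°; runs shorter than 3 and
chain-break residues fall back to coil), which is sufficient for the
four-way 30% interface label (H/S/HS/C per side) without an external
program. It is not a DSSP replacement: no hydrogen-bond pattern
analysis, no 3₁₀/π distinction.

## Pockets

A united-atom methyl probe (ε 0.16 kcal/mol, σ 3.6 Å, Lorentz–Berthelot
combination with per-element parameters) is evaluated on a 0.9 Å grid
over the surface shell; points with summed Lennard-Jones 12-6 energy
≤ −1.4 kcal/mol within 8 Å of protein atoms are kept, single-linkage
clustered at 1.6 Å, ranked by ascending total energy, and the ten
strongest clusters retained. Pockets "at the interface" are those with
at least one probe point within 2.0 Å of a superposed inhibitor atom.
All energy constants are configuration values: the original server's
internal thresholds are unpublished, so pocket counts and volumes are
order-of-magnitude descriptors here, not reproductions — flat surfaces
give no pockets, carved cavities give exactly one each, and a
surface-lying inhibitor on a flat target yields zero interface pockets
(the ZipA-like situation), all of which the tests pin down.

## Superposition

CA atoms are paired by chain/residue number (falling back to residue
number alone when chain naming differs), and the optimal least-squares
rigid transform is computed by the Kabsch procedure (via
`scipy.spatial.transform.Rotation.align_vectors`); the RMSD over paired
CAs after fitting is the conformational-change descriptor. For NMR
entries, model 1 is used and recorded in report provenance.

## Statistics and classification

The group comparison statistic is the unequal-variance two-sample
t = (M₁−M₂)/√(Var₁/n₁+Var₂/n₂) with n−1 variances; |t| > 1.34
corresponds to ≈90% confidence at the reference group sizes. The
reference transient-dimer group enters only as caller-supplied summary
constants — its member structures are not recomputed.

PCA standardizes each descriptor (the six span Å², Å³, counts and
percentages) and eigendecomposes the correlation matrix; components are
sign-fixed by making the largest-magnitude loading positive. Clustering
is k-means, k = 3, best of 50 restarts, labels canonicalized by centroid
order along the first component. **Clusters are formed in the plane of
the two leading components** (the biplot plane): full-dimensional
k-means on the reference panel splits the class-I group and never
isolates the subtilisin/trypsin protease cluster, whereas biplot-plane
clustering reproduces the reference memberships — all six class-I
complexes together, the three subtilisin and one trypsin complexes as
their own cluster — in 100/100 random seeds using the five printed key
descriptors. `n_components=None` restores full-dimensional clustering.
The per-complex charged-residue percentages are not part of the
published panel (only group moments, 18.9 ± 13.8% vs 27.0 ± 12.5% for
transient dimers, are printed); injecting synthetic per-complex values
drawn from those moments adds an uninformative dimension and degrades
class-I co-clustering to ~40%, which says something about noise
injection, not about the published clustering — the bundled panel
therefore stores the column as missing.

The druggability comparison places each query descriptor on the
reference distribution as z = |x−mean|/sd; ≤ 0.5 sd is "very close",
≤ 1.0 sd "close" (thresholds chosen to operationalize the qualitative
server behavior; both configurable). The overall score is the mean z.
The weak/strong affinity indication is nearest-class-centroid in the
same standardized space, standing in for unpublished reference
parameter vectors of weak and strong transient dimers.

## Reference panel

The bundled CSV transcribes the 17-complex reference table (families,
classes, inhibitor counts, affinities with Ki flagged, and the twelve
descriptor columns), decimal commas normalized to dots. Missing
affinities are stored as missing, never zero. Integrity is enforced on
load: 17 records, 14 families, 6/11 class split, 56 inhibitors summed
over families, and class consistency with the segment rule. One
transcription note: the class II interface-area standard deviation is
printed as 151 in the table and 150 in the running text; the table value
is used. Aggregation always uses unweighted means and n−1 variances,
which reproduce every printed group mean/sd to one unit in the last
printed digit.

## Synthetic data

`build_toy_complex` emulates the study's structural situations, not
proteins. Receptors are slabs of CA-only pseudo-residues (4 Å pitch)
whose sequence numbering snakes through each layer so that a contact
patch maps onto few sequence segments; class-I partners are real ideal
backbones (helix −57°/−47°, strand −120°/+120°, NeRF-built with standard
bond geometry, pseudo-Cβ spheres) laid into a one-row groove; class-II
partners are CA-only serpentines whose raised turns exceed the segment
gap bound, making each contact strand its own segment; the flat variant
lays the fragment on an ungrooved surface. Hydrogen-bond sites, salt
bridges and charged residues are created by renaming pseudo-residues and
attaching functional atoms at canonical distances (N···O 2.8 Å donors,
3.5 Å acid–base pairs), with a deterministic feasibility filter that
keeps every added atom clear of both partners. Each toy provides the
protein/protein, unbound (0.2 Å seeded jitter; expected CA RMSD
0.2·√3 ≈ 0.35 Å) and protein/ligand forms, with the ligand a truncated
copy of the partner. All randomness flows from the spec seed and output
is byte-reproducible.

What the toys establish: every pipeline stage runs end-to-end on valid
PDB input; engineered contacts are found by the detectors; the class
rule, segment counting, secondary-structure labels and the
zero-interface-pocket behavior of flat targets come out as designed; and
the class-I vs class-II contrasts point in the reference direction
(smaller area, fewer segments, lower hydrogen-bond density for
class I). What they do not establish: absolute agreement of descriptors
with any real complex — pseudo-atom slabs have no side-chain packing,
no waters, no crystallographic noise — so per-complex descriptor values
on real structures are validated separately (see below).

`simulate_descriptor_table` draws class-conditional independent
Gaussians at the reference class moments, truncated to valid ranges
(counts rounded and floored, percentages clipped to [0, 100]).
Independence across descriptors is a deliberate simplification; no
correlation structure is claimed.

## Problem sizes and scope of the checks

The default test suite and the acceptance script use desk-scale inputs:
toy complexes of 150–450 atoms, 10⁴-draw moment checks, 10³-replicate
power simulations, 40–50-seed clustering stability runs. Quantities that
depend on the original third-party tool stack at full numeric precision
are out of scope by design: exact per-complex descriptor values
(different SASA/gap/pocket engines), the published t-value bar heights
against the transient-dimer reference (that group's variances are not
printed), absolute pocket counts/volumes, and the exact geometry of the
published PCA biplot. The one check requiring a real structure — five
salt bridges across the IL-2/IL-2Rα interface (PDB 1z92), including
Glu62–Arg36 — downloads the public coordinates at test time (or uses a
local copy under `tests/data/1z92.pdb`) and fails, rather than skips,
when neither is available.
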