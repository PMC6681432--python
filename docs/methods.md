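# Methods

## The model

A topological water network (TWN) is a cycle of 3–6 water molecules in
the water–water hydrogen-bond graph. The package treats TWN detection
as three composable stages — criterion, enumeration, assignment — each
of which can be validated independently.

### Hydrogen-bond criterion

Two water molecules are bonded under one of two criteria, chosen by
the nature of the input:

* **Energy (frames mode).** The rigid TIP3P pair interaction: nine
  site–site Coulomb terms (charges q(O) = −0.834 e, q(H) = +0.417 e,
  conversion constant 332.0636 kcal·Å·mol⁻¹·e⁻²) plus a single
  oxygen–oxygen Lennard-Jones term with A = 582 000 kcal·Å¹²·mol⁻¹ and
  C = 595 kcal·Å⁶·mol⁻¹. The bond threshold is −2.25 kcal·mol⁻¹,
  the minimum of the TIP3P pair-energy distribution; the comparison is
  inclusive (≤), a convention we fix because the boundary case is
  measure-zero in practice and an inclusive cutoff is the conservative
  reading of "criterion of −2.25". Waters must carry two explicit
  hydrogens; waters without hydrogens are rejected rather than
  silently downgraded to the distance criterion.
* **Distance (crystal mode).** Crystal waters are deposited as
  oxygen positions only, so an energetically significant hydrogen bond
  is inferred from an O–O separation strictly below 3.5 Å. The strict
  inequality follows the wording "distances of < 3.5 Å"; it matters
  only on a measure-zero boundary.

No angular condition is applied in either mode: bonds are defined
purely by energy or O–O distance.

Periodic boundary conditions: the minimum-image convention is applied
for orthorhombic boxes only, and only in frames mode (a box read from
a crystal structure's CRYST1 record is never used to wrap crystal
waters — no symmetry-mate expansion is attempted). The image shift is
computed from the oxygen–oxygen displacement and applied to the
partner molecule as a rigid unit, preserving its internal geometry.

Water records closer than 0.5 Å are duplicates (e.g. partial-occupancy
artifacts) and are collapsed to the lowest-id record with a warning.

The all-pairs criterion scan is pruned with a KD-tree: under default
parameters no pair beyond 6 Å can bond under either criterion, so the
candidate search radius is 6 Å (the distance cutoff itself in distance
mode). The tests verify pruned ≡ naive all-pairs on random boxes up to
n = 200.

### Ring enumeration

Cycles of size 3–6 are enumerated on the hydrogen-bond graph and
deduplicated by canonical form — the lexicographically smallest
rotation/reflection of the member tuple — so each polygon is counted
exactly once and output order (size, then canonical tuple) is
byte-reproducible. Two policies are provided:

* **chordless** (default): a cycle is reported only if no edge joins
  two non-adjacent members. A chorded 4-cycle is geometrically two
  triangles; reporting the square as well would double-count the same
  waters as a larger species.
* **all_simple**: every simple cycle of a requested size. Retained
  because the counting convention for chorded rings in surveyed data
  is not fixed by the criterion itself; result tables record the
  policy that produced them.

Enumeration is delegated to networkx (`chordless_cycles` /
`simple_cycles`, both length-bounded); the test suite checks
equivalence against an independent brute force that scans every vertex
subset of sizes 3–6 for Hamiltonian cycles (and chordlessness under
that policy) on hundreds of random graphs.

### Hydration shell and assignment

Rings are detected among waters whose oxygen lies within 10 Å of the
residue reference atoms. The default reference is the C-alpha atom;
`all_heavy` switches to every residue heavy atom. 10 Å is wide enough
to cover the first and second hydration shells, and TWNs are treated
as one unit, so no attempt is made to resolve per-layer membership.
Rings are built only from shell waters: a ring partially outside the
shell is not reported.

Each ring is assigned to exactly one residue heavy atom: the candidate
(element O, N, C or S; hydrogens never; ACE/NME cap atoms excluded by
default) with the smallest Euclidean distance to any of the ring's
oxygens. Exact distance ties break to the lowest atom serial, making
assignment deterministic. Region is backbone (N, CA, C, O, OXT) or
side chain (all other heavy atoms).

The crystal path has no per-residue shell pre-selection (all crystal
waters of the structure participate in graph construction); instead a
detected ring is admitted only if its minimal distance to a residue
heavy atom is within the shell radius, keeping the frames and crystal
paths comparable.

### Aggregation

Assignments aggregate into a residue-type × atom-class table with rows
O, N, C, S, Total, (O,N)/Total, C/Total and S/Total, in three scopes:
combined, backbone, side chain (backbone + side chain = combined,
column by column). Ratios are rounded half-up to two decimals
(215/344 → 0.63). Zero counts render blank; a ratio renders only when
its numerator is non-zero. Columns follow the Kyte–Doolittle
hydropathy order (Ile most hydrophobic … Arg most hydrophilic), which
groups hydrophobic and hydrophilic residues visually. His tautomer
names (HSD/HSE) are kept as separate columns when the input uses them;
generic HIS stays one column.

### Dataset filter

For crystal-structure corpora, files pass three rules in order, each
file charged to the first rule it fails: (1) protein content — files
with no amino-acid residues (e.g. nucleic-acid-only) are dropped;
mixed protein–nucleic complexes are kept; (2) crystal waters present;
(3) resolution strictly better than 1.6 Å, the regime where a
continuous surface hydration layer is typically resolved. Unknown
resolution fails rule 3 (the kept corpus is explicitly X-ray,
high-resolution). Unparseable files are counted and logged, never
silently skipped, and the report reconciles: inputs = kept + Σ dropped.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| energy cutoff | −2.25 | kcal·mol⁻¹ | inclusive; configurable |
| O–O cutoff (crystal) | 3.5 | Å | strict <; configurable |
| shell radius | 10.0 | Å | first + second hydration shells |
| shell reference | C-alpha | — | `all_heavy` available |
| ring sizes | 3–6 | — | hard bound; larger rings out of scope |
| policy | chordless | — | `all_simple` available |
| resolution cutoff | 1.6 | Å | strict < |
| TIP3P A, C | 582000, 595 | kcal·Å¹²/⁶·mol⁻¹ | LJ on oxygen only |
| charges | −0.834 / +0.417 | e | neutrality enforced |
| duplicate threshold | 0.5 | Å | collapse with warning |
| frame stride | 1 | — | 2 converts 5 ps spacing to 10 ps |

## Synthetic data: what it emulates, what it does not

The generator stands in for solvated capped-amino-acid snapshots. A
scene contains an idealized alanine capped with ACE and NME (hard-coded
heavy-atom geometry with plausible bond lengths — a fixture, not a
force-field build), planted water rings and noise waters inside a box.
Ring oxygens sit on a regular polygon (default side 2.8 Å, a typical
hydrogen-bonded O–O distance); each water donates one hydrogen toward
its clockwise neighbor along the O–O axis and points its free hydrogen
outward along the ring radial, with rigid TIP3P internal geometry
(O–H 0.9572 Å, H–O–H 104.52°). Generation *certifies* each ring
against the package's own criteria — every adjacent pair must pass the
energy criterion (when hydrogens are placed) and the distance
criterion, every non-adjacent pair must fail both — and raises if
certification fails, so planted topology is ground truth by
construction, not by assumption. Noise waters keep at least 6 Å from
every other water, beyond the reach of either criterion, so they can
neither join nor bridge rings. Scene placement is stochastic with a
bounded retry budget; if a pass fails, the scene restarts from a
sub-seed derived from the scene seed, keeping generation fully
deterministic per seed. Ground truth records ring memberships and the
intended nearest atom with its ambiguity margin (nearest-atom recovery
is only asserted where the margin exceeds 0.1 Å, since a near-tie is
legitimately decided by the serial tie-break).

What the generator does **not** emulate: liquid-water disorder (real
shells contain transient, distorted rings at the criterion boundary),
water–protein hydrogen bonds, ring species embedded in a continuous
bulk network, thermal geometry fluctuations, crystallographic
artifacts (partial occupancy, symmetry mates). Passing the recovery
suites therefore demonstrates correctness of the detection machinery —
criteria, enumeration, assignment, bookkeeping — on unambiguous
topology; it does not validate conclusions about real hydration
statistics, which depend on sampling real frames.

## Reference tables and their arithmetic

Published per-residue 3-ring count tables (an MD survey over the 20
amino acids and a crystal-structure survey) ship with the package as
reference data. The per-class O/N/C/S counts are the raw data; Totals
and ratio rows are recomputed by the package's own table arithmetic
and compared cell-by-cell at printed precision. 490 of 492 printed
cells reproduce exactly under half-up rounding; two cells of the MD
combined table (C/Total for Asp and Lys) are internally inconsistent
with their own class counts by one unit in the second decimal
(129/344 = 0.375 printed as 0.37; 183/347 = 0.527 printed as 0.52 —
no standard rounding yields the printed values), and the tests assert
agreement within 0.01 for exactly those two cells.

## Numerical choices and degenerate inputs

* Coordinates are float64 throughout; PDB I/O is via gemmi and
  round-trips positions to the format's 3-decimal precision.
* Coincident oxygens (r < 10⁻⁶ Å) raise a singular-geometry error in
  the pair energy; near-duplicates (< 0.5 Å) are collapsed upstream.
* Empty inputs degrade gracefully: zero waters give an empty graph,
  zero assignments an all-blank table; a frame with no reference atoms
  is a configuration error rather than an empty shell.
* Altlocs: blank or conformer 'A' kept, others discarded. Multi-MODEL
  crystal files use model 1. Stride-k reading keeps models 1, k+1,
  2k+1, …
* Problem sizes in the validation suites — 100 random graphs of up to
  15 vertices against the subset brute force, 100 seeded scenes,
  all-pairs graph comparisons up to 200 waters — were chosen so the
  independent oracles (combinatorial enumeration, naive O(n²) scans)
  remain exact and fast while covering the regime the detector
  actually operates in (a 10 Å shell holds well under 200 waters).

## Known limitations

* Orthorhombic boxes only; triclinic minimum image is not implemented.
* No symmetry-mate expansion for crystal structures: rings spanning a
  crystallographic interface are seen only as deposited.
* Water models other than TIP3P (TIP4P, SPC/E) and water–protein
  hydrogen bonds are out of scope.
* The distance criterion cannot distinguish donor from acceptor, so
  crystal-mode graphs are blind to hydrogen-bond directionality.
* mmCIF and binary trajectory formats (XTC/DCD) are not read; inputs
  are PDB / multi-MODEL PDB.
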