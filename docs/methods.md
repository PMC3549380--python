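# Methods

## The network model

Each residue contributes one node placed at the unweighted mean of its
heavy side-chain atoms (backbone N/CA/C/O and terminal OXT excluded, CB
included); glycine, with no side-chain heavy atom, uses its CA position.
Hydrogens are ignored — X-ray structures usually lack them — and the
highest-occupancy alternate location is kept (ties resolved toward altloc
A).  Two nodes are linked when their centroids are strictly closer than the
cutoff r_c, default 6.5 Å, the radius used in deriving the contact
statistics behind the potential; the comparison is exclusive (r = r_c is
not a contact).

Sequence neighbours are a special case.  The peptide bond is a real,
permanent interaction that the distance-based criterion can miss, so
residues i and i±1 of an unbroken chain are always linked, with weight 0
(the contact potential describes non-bonded statistics, not covalent
bonds).  A chain break — a gap in author numbering or a CA–CA separation
above 4.5 Å — suppresses the bond.  This choice guarantees that the network
of any intact chain is connected, which in turn keeps the average
shortest-path length well defined.  It is an interpretation: the weight-0
assignment for covalent links is explicit in the model, their existence
beyond the cutoff is implied by their finite distance.

Link weights are the contact energies w_ij of the two residue types
(dimensionless, RT units).  Negative w is net attraction ("similar"
weight), positive w net repulsion ("dissimilar").  Common variant residues
are mapped before lookup (MSE→MET, SEC→CYS, CHARMM/AMBER histidine
tautomers→HIS); anything unmappable is skipped with a warning in lenient
mode or raises in strict mode.

## The bundled synthetic potential

The model calls for a self-consistent contact potential spanning
[−1.19, 0.76] over the 210 residue-type pairs.  The table shipped with the
package is a **synthetic stand-in**, not the experimentally derived matrix:
it is built deterministically as
`raw_ij = −h_i·h_j + 0.35·q_i·q_j` (h = Fauchère–Pliska hydrophobicity
normalized to [0, 1], q = formal side-chain charge with His at +0.5),
affinely rescaled so the global extremes equal −1.19 and +0.76 exactly, and
rounded to two decimals.  It reproduces the structural features that matter
to the network model — hydrophobic–hydrophobic pairs strongly attractive
(minimum at TRP–TRP), like-charged pairs most repulsive (maximum at
ARG–ARG), opposite charges attractive, both signs well represented
(99 attractive / 111 repulsive pairs), and a sub-(−1) tail that exercises
the definition-2 clamp — but its individual entries carry no statistical
authority.  Conclusions that depend on specific pair energies require a
real potential file, accepted by `load_potential_table(path)` in full or
lower-triangular text form.  The loader's range gate (global min/max must
equal −1.19/0.76 to 1e-9) is enforced for the bundled table and optional
for user tables.

## Distance definitions and numerical choices

Definition 1 maps attraction through 1/(1 − w) (stronger attraction, shorter
distance; bounded in [1/2.19, 1)) and repulsion through 1 + w (bounded in
(1, 1.76]); both branches meet continuously at w = 0.  Definition 2 treats
every weight as dissimilar, (1 + w)/2.19; definition 3 treats every weight
as similar, 1/(1 − w).  The divisor 2.19 equals 1 + |w_min| but is treated
as an opaque, configurable normalisation constant.

Definition 2 yields non-positive distances for w ≤ −1 (possible: the table
minimum is −1.19).  Those entries are clamped to ε = 1e-6 and the clamp
count is reported on the distance matrix; clamping preserves the ranking
"strong attraction = very short" while keeping Dijkstra's nonnegativity
precondition.  Definition 3 would be singular at w = 1, which the range
gate makes unreachable; it is asserted defensively.  Absent links carry an
infinite sentinel that the shortest-path layer treats as "no edge", never
as a numeric distance.

Shortest paths use Dijkstra (scipy's for distances; an in-package
Brandes-style accumulation for betweenness, because tie counting needs a
tolerance).  Two path lengths tie when they agree within a relative 1e-9;
exact floating-point equality would make tie detection depend on summation
order.  Betweenness counts unordered pairs with endpoints excluded; the
alternative ordered convention would double every value and cancel in the
Z-scores, which is what downstream analysis consumes.  Z-scores use the
population standard deviation (sample available by flag); a zero-spread
betweenness vector yields all-zero Z with a warning rather than NaN.

The average shortest-path length L averages finite unordered pairs only and
is always reported together with the connected fraction, so a disconnected
graph cannot masquerade as a short one.  The weighted clustering
coefficient evaluates the ordered-pair double sum, which collapses
algebraically to `Σ_j |a^w_ij| (A²)_ij / [S_i (K_i − 1)]`; nodes with
K < 2, or with only covalent (zero-strength) links, get C_i = 0.  Covalent
links count toward K_i and the triangle indicator but contribute zero
weight to both numerator and strength, per the definitions taken literally;
whether they should be excluded from K is genuinely open, and the
convention is surfaced here rather than hidden.

## Random-network baselines and the small-world readout

C_r = ⟨K⟩/N and L_r = ln N / ln⟨K⟩ are the standard Erdős–Rényi-style
expectations for a graph of the same size and mean degree.  The summary
reports C/C_r and L/L_r without a pass/fail verdict: the small-world
signature is a large clustering ratio at an O(1) path ratio.  L_r is
undefined for ⟨K⟩ ≤ 1 and reported as missing.

## What the synthetic generator emulates — and what it does not

`make_compact_chain` produces a self-avoiding bead chain (one pseudo-atom
per residue, 3.8 Å virtual bonds, 4.0 Å non-bonded floor) confined to a
sphere sized so the realized radius of gyration tracks the folded-protein
scaling Rg ≈ 2.2 n^0.38 Å; inside the sphere the walk is unbiased, outside
it is pulled back proportionally to the excursion.  Residue types are
sampled from the average globular-protein composition with two layers of
realism: per-chain composition drift (Dirichlet with concentration 50× the
mean frequencies — protein sets vary in bulk composition) and a noisy
hydrophobic core (types assigned to beads by burial rank after perturbing
their hydrophobicity with 0.8 kcal/mol Gaussian noise — folded proteins
bury hydrophobics, and the model's attractive core links arise from exactly
that layering).  At these settings the chains reach mean degree ≈ 5–6.5 at
the 6.5 Å cutoff, matching folded-protein packing density.

`make_expansion_series` dilates a base structure uniformly about its
centroid — the minimal surrogate for an unfolding pathway, in which
contacts break monotonically as the structure loosens.  It is valid only up
to the factor 4.5/3.8 ≈ 1.184: beyond that the virtual backbone itself
crosses the chain-break threshold, an artifact (bond scission) no real
unfolding has, and the generator warns.  Study-scale profiles therefore use
factors 1.0 → 1.18.

`make_toy_complex` joins two compact lobes (55 residues each) through a
3-residue bridge, so bridge-zone residues carry all inter-lobe shortest
paths and reach extreme betweenness, then verifies itself: it computes the
bare chain's Z-scores, takes the top-Z residue, and docks a 5-atom ligand
within contact range of one of that residue's network neighbours while
keeping the residue itself out of range.  The returned complex therefore
always contains a direct-contact residue and a one-hop-mediated
high-centrality residue.  Geometry draws failing the Z ≥ 3 gate are redrawn
deterministically from the seed.

None of these fixtures is a physical protein: there is no backbone
geometry, no secondary structure, no sequence–structure coupling beyond the
burial layering, and ligands are featureless carbon clusters.  Passing
tests on them demonstrates the correctness and qualitative behaviour of the
network machinery (connectivity, small-world ratios, monotone unfolding
response, contact classification), not quantitative agreement with any real
protein set; quantities tied to real structures — the printed L–Rg
correlations of a curated 197-protein set, the FKBP/FK506 contact counts —
require the corresponding real inputs.

## Study-scale choices

The bundled analyses use panels the package can regenerate anywhere: 30
compact chains with lengths evenly spaced over 51–200 residues (seeds
0–29) for the small-world and size-correlation readouts, and a 20-frame
1.0 → 1.18 expansion of a 100-residue chain for the unfolding profile.  On
the unfolding surrogate, definition 1's L rises monotonically and, in
absolute units, faster than definition 2's — definition 2 compresses all
distances by 2.19 and maps strong attractions to near-zero lengths, so its
curve starts far lower and its *relative* rise can exceed definition 1's
even though its absolute response is smaller.

## Known limitations

* The bundled potential is synthetic (above); every quantitative statement
  about specific residue pairs inherits that caveat.
* Trajectory input is multi-model PDB (or file lists); binary MD formats
  (XTC/DCD) are an extension point, not core.
* The atom-contact cutoff for hot-spot classification defaults to 4.5 Å
  with 5.0 Å as the documented alternative; published per-complex contact
  counts can shift between the two, so both are checked when reference
  counts are available.
* Structures are taken as-is: no repair, protonation or missing-atom
  reconstruction.
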