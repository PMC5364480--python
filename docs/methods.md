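# Methods

`pinevol` reimplements, as a tested pipeline over synthetic data with known
ground truth, an analysis of how a protein-protein interaction network (PIN)
of plant MADS-domain transcription factors rewires across whole-genome
duplications, and how the conformational flexibility and backbone geometry of
a hub protein relate to its interaction promiscuity.  This note records the
models, the parameters that matter, the numerical conventions, and what the
synthetic data do and do not establish.

## Network model and generative process

A PIN is an undirected graph over protein identifiers in which homodimers are
self-pair edges ("looped lines").  Each network carries an epoch time in
million years ago (mya); the default anchors (180, 120, 109 mya — origin of
angiosperms, origin of eudicots before the gamma triplication, and the
Asterid/Rosid split) are plain configuration values.

The generator (`synth.simulate_pin_evolution`) starts from an Erdos-Renyi
draw over all unordered pairs including self-pairs (initial edge probability
`p0`, default 0.25, in the range of the observed network densities) and
evolves edge presence in 1-mya steps: an absent pair gains with probability
`gain_rate` per mya, a present edge is lost with probability `loss_rate` per
mya (defaults 0.001 and 0.005 — small enough that a ~10-mya window rewires a
few percent of pairs, the regime the epoch comparisons live in).  At a
polyploidy event every node is copied `multiplicity` times and copies
inherit edges **all-versus-all**: an ancestral edge (A, B) implies an edge
between every copy of A and every copy of B, and an ancestral homodimer
implies every pair (loops included) among the copies.  With probability
`subfunc_prob` a duplicated node instead partitions its ancestral partner
set among its copies (each partner assigned to exactly one copy, uniformly),
so that in ancestral coordinates the union of the copies' partner sets
equals the parent's and the pairwise intersections are empty — the additive
signature that the subfunctionalization check tests for.

### Ground-truth rates

The emitted truth carries expected comparison-based rates rather than the
raw hazards: comparing two snapshots counts an edge as *gained* when it is
absent at the window start and present at the end, so within-window
flip-flops make the naive hazard biased as an estimand.  Per pair, presence
follows a two-state Markov chain; `true_gain_rate` is the exact
`E[gained] / (potential pairs x window length)` obtained by propagating the
realized start-of-window density through that chain (analogously for
losses), averaged over windows without polyploidy events.  When every
window contains an event the raw hazards are reported instead.  The rate
estimator (gained or lost interactions divided by potential interactions
times divergence time) is unbiased against this estimand by construction,
which is what the 20-replicate recovery suite verifies.

### Density conventions and polyploid rescaling

Density is observed over potential interactions.  Three conventions are
computed because they genuinely disagree on self-pairs:

- `pairs` (default): potential = n(n+1)/2, each edge counts once;
- `pairs_noself`: loops excluded, potential = n(n-1)/2;
- `matrix`: symmetric-adjacency convention, potential = n^2, a non-loop
  edge counts twice, a loop once.

Under all-versus-all inheritance the fiber of a non-loop ancestral edge has
size m^2 while a loop's fiber has size m(m+1)/2, so an all-copies rescaling
preserves the observed/potential ratio **exactly only in the `matrix`
convention** (where both fibers weigh m^2); under the default `pairs`
convention preservation is exact only when the loop fraction of the edge set
equals the loop fraction of the potential set, and otherwise holds up to an
O(1/n) correction.  The conservation suite asserts exactness in the matrix
convention and approximate preservation in the default one.  Redundant-node
removal after rescaling takes an explicit keep-list or, with `target_size`,
a deterministic round-robin over ancestors (lexicographic order), since
nothing in the data dictates which copies to drop.

In cross-epoch comparison, a descendant edge is *conserved* when its
ancestral image is an edge, otherwise *gained* (edges with unmapped
endpoints count as gained); an ancestral edge is *lost* when no image pair
survives.  Lost edges are reported in ancestral coordinates — they have no
descendant image by definition.  `conserved + gained` always partitions the
descendant edge set, giving the exact inverse check used in the tests.

## Interaction calling

Assay tables carry beta-galactosidase activity in Miller units, with
replicates, for every ordered bait-prey(-mediator) combination, plus
empty-vector rows (reporter leakiness — pooled, they form the background)
and per-bait auto-activation rows (bait + empty prey).  Replicate noise in
the generator is log-normal with a coefficient-of-variation parameter
(default 0.15, typical of replicate reporter assays): Miller units are
positive and noise acts multiplicatively.  No distributional claim is made
for real tables; the caller itself only uses means and a location test.

A dimeric pair is positive when a one-sided Welch t-test of its replicates
against the pooled background rejects at `alpha` (default 0.05) **and** its
mean exceeds `min_fold` (default 2) times the background mean.  Calling is
symmetric: a pair is positive if either bait-prey orientation is.  A bait
whose auto-activation control is significantly above background poisons its
orientation; a pair is excluded (`autoactive_excluded`) only when no clean
orientation remains, since the reciprocal orientation with a clean bait
still reports on the interaction.  Exact ties and zero-variance degenerate
cases resolve to negative.

A mediated (three-hybrid) interaction subtracts the dimeric network: delta =
mean(Y3H) minus the pair's Y2H mean when the pair was Y2H-positive, or minus
the pooled background otherwise (a Y2H-negative pair has no dimer signal
beyond leakiness).  The call is positive when the pair is Y2H-negative but
Y3H-positive against the Y3H background, or when the enhancement is
significant: a one-sided one-sample t-test of the Y3H replicates against the
Y2H baseline at `alpha` with delta above `min_delta` (default 0).  The
one-sample form is used because Y2H replicates are not available at call
time, only calls; this treats the baseline as exact and therefore inflates
the enhancement false-positive rate slightly when deltas are small — raising
`min_delta` to a few background standard errors (the analysis drivers use
1.5 Miller units) restores clean recovery.  Negative deltas always yield a
negative call (lost/false-positive signal), and an auto-active mediator
invalidates the whole table.

## Conformational flexibility

Conformer ensembles are lists of potential energies (kcal/mol).  Boltzmann
probabilities use P_i proportional to exp(-(E_i - E_min)/kT) (min-shifted,
so numerically stable and origin-invariant), and the conformational entropy
is S = -R sum P_i ln P_i with R = 1.98720 cal mol^-1 K^-1.  Entropies are
molar (cal K^-1 mol^-1): per-molecule Boltzmann-constant units would be
~10^23-fold smaller than the few-cal/K values this descriptor is meant to
take.  Default temperature is 298.15 K.  The size of the conformational
space is the count of minima within `minima_window_kcal` (default 5
kcal/mol) of the global minimum; the window is a configuration choice, since
"low-energy" is defined by the upstream search protocol, not by the
ensemble.  Ensemble comparisons (fold-change of minima counts, delta-S)
require a common temperature and refuse otherwise.  The generator's
reference entropy is evaluated directly in long-double precision,
independently of the analysis path.

Published minima counts and entropies for the two linker peptides (645 vs
269 minima, 3.72 vs 2.90 cal/K) depend on the original force-field search
and are not reproducible from energies alone; the synthetic comparisons use
those ensemble sizes only to shape a rigid-vs-flexible contrast, and no test
asserts those entropy values.

## Structure geometry

Coordinates are Angstrom; PDB I/O goes through Biopython (altlocs resolve to
the highest-occupancy conformer, ties toward 'A').  Residue selections use
author numbering with closed intervals (e.g. K1 = residues 98-111), matching
how subdomain ranges are printed.

- **Superposition** is the Kabsch algorithm (SVD with determinant
  correction, proper rotation guaranteed); inputs with fewer than 3 pairs or
  collinear selections are rejected.  Trajectory RMSD is per-frame against a
  reference frame or structure, optionally C-alpha-only, superposed by
  default.
- **SASA** is Shrake-Rupley quadrature with a deterministic golden-spiral
  point lattice (default 960 points, probe 1.4 A) and a documented,
  overridable radii table (C 1.7, N 1.55, O 1.52, S 1.8, H 1.2, P 1.8 A).
  All atoms occlude; only selected atoms contribute area.  Exactly
  coincident atoms expose a single sphere's surface, attributed to the
  lowest-index atom (a deterministic degenerate-input policy).
- **Dihedrals** follow the IUPAC sign convention; termini and chain gaps
  (C-N distance above 2 A) report absent angles, never interpolations.
  omega(i) is the torsion of the peptide bond preceding residue i, so a
  cis-proline has omega near 0.
- **Turn classification**: beta (4-residue) windows gate on
  C-alpha(i)-C-alpha(i+3) < 7 A with the inner residues not both inside a
  tight ideal-helix box (within 15 deg of phi=-57, psi=-47 — deliberately
  narrow so near-helical turn conformations still classify); canonical types
  use the standard Hutchinson-Thornton (phi, psi) table at a +/-30 deg
  tolerance with one angle allowed to 1.5x tolerance.  Cis-proline at i+2
  restricts candidates to the VIa1/VIa2/VIb entries; a gated window matching
  no candidate is type IV, the residual class — which is how the printed
  LGPL loop dihedrals (-50, -51, -62, -20 with cis-Pro) classify.  Gamma
  (3-residue) and alpha (5-residue) turns gate on the i->i+2 (< 5.8 A) and
  i->i+4 (< 6.5 A) C-alpha distances; "pseudo" variants are windows passing
  the geometric/H-bond gate without the canonical dihedral signature.  The
  pseudo gates are implementation definitions — no community standard fixes
  them — and are labelled as such.
- **Polar contacts**: a salt bridge is the minimal Asp/Glu carboxylate-O to
  Arg/Lys/His side-chain-N distance under 4.0 A; hydrogen bonds are
  donor-acceptor heavy-atom distances under 3.5 A from documented donor and
  acceptor tables, with no angle term (distances are what the source data
  report; angle filtering would add a criterion the data cannot check).

The backbone fixture builder extends a chain with ideal bond lengths and
angles (Engh-Huber-style averages) from per-residue (phi, psi, omega), so
dihedral recomputation round-trips to well under a degree; trajectory
fixtures are rigid transforms plus isotropic Gaussian noise, whose expected
superposed RMSD (sigma * sqrt(3(1 - 2/N))) gives a closed-form check.

## What the synthetic data do not show

The generator reproduces the *structure* of the study's inputs — replicate
Miller tables with controls, epoch-stamped networks with ortholog maps,
conformer energy lists, backbone coordinates — under clean parametric
assumptions: independent log-normal replicate noise, independent per-pair
edge dynamics, ideal backbone geometry.  Real assay tables have
plate/batch effects and correlated auto-activation; real networks evolve
with lineage-specific and correlated gains; real conformer sets carry
force-field idiosyncrasies.  Passing tests therefore establishes that the
statistics and geometry kernels are correct and calibrated on their stated
models, not that the biological conclusions of any particular dataset
follow.

## Problem sizes

Default suites use 20-45 protein networks, 20 replicate histories for rate
recovery, ~1000 pairs for caller calibration, 100 instances x 10,000
rotations for superposition optimality, and 960-point SASA quadrature —
sizes at which every check runs in seconds while keeping binomial/sampling
error well inside the asserted tolerances.
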