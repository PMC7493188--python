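# Methods

## Consensus model

Given *n* docking models of the same complex, consistently renumbered so
that corresponding residues carry identical chain labels and numbers, an
intermolecular residue contact is any pair of residues on different
chains with at least one heavy-atom pair at distance < 5 Å. Writing
CR_kl for the fraction of models containing contact (*k*, *l*), model
*i* with contact set of size M_i receives

    S_i = Σ CR_kl over its contacts,     S̄_i = S_i / M_i.

Models are ranked by S̄_i descending. Ties are broken by M descending
(richer interface preferred) and then by model identifier, so the
ranking is a total order independent of input order. S̄ of the
top-ranked model is the Maxscore. Hydrogens and heteroatoms are ignored
everywhere (contacts, clashes, surfaces): the analysis is heavy-atom,
protein-only. All distance comparisons are strict (`<`); boundary hits
are measure-zero for real coordinates.

The central assumption is sociological rather than physical: an
ensemble aggregated from many independent predictors is enriched in the
correct interface whenever the target was tractable, so frequency is a
proxy for correctness. The method inherits the corresponding failure
mode — when the ensemble holds no consensus (hard targets), the top of
the ranking is arbitrary — which is why the Maxscore is used as an
explicit reliability signal rather than trusting the ranking blindly.

### Homodimer symmetrization

For two-chain targets with identical sequences the A/B labeling of a
pose is arbitrary. Contact keys for such targets are canonicalized with
the smaller residue index on the first chain, so a pose and its
chain-relabeled mirror have identical contact maps. Without this, the
consensus would split between the two labelings of the same interface.
Higher-order oligomers are scored on a designated two-group chain
partition; symmetry enumeration across multiple equivalent interfaces
is out of scope.

## Filtering and renumbering

Models are discarded for being unreadable, atom-free, single-chain,
sequence-mismatched, or contact-free, and every discard is itemized.
The sequence test aligns each model chain to each target chain with a
global alignment, identity matrix, gap open 10 / extend 0.5, free end
gaps; identity = matches / aligned columns, coverage = aligned target
positions / target length. A chain must reach identity ≥ 0.90 **and**
coverage ≥ 0.70 to be assignable; chains are assigned to target labels
greedily by identity with ties broken by file order. The stricter
and-reading of the two thresholds is deliberate: a model failing either
cannot be renumbered reliably. Aligned residues take the 1-based target
position; unaligned residues keep their coordinates but are excluded
from contact analysis; insertion codes are flattened.

## Clustering

Pairwise model distances are Hamming distances between contact maps —
the number of differing contacts — assembled in condensed form via the
binary contact-incidence matrix (d_ij = M_i + M_j − 2|∩|). Agglomeration
is complete linkage (inter-cluster distance = maximum member-pair
distance), implemented in-package with Lance–Williams max updates
because reproducibility on integer distances requires a defined tie
rule: among equal-height candidate merges, the pair whose clusters
contain the smallest original indices wins. Flat clusters come from the
maxclust criterion (smallest cut height yielding ≤ *t* clusters, via
`scipy.cluster.hierarchy.fcluster`) with *t* = ⌊*n*/10⌋, minimum 1 —
the divisor keeps the procedure independent of ensemble size, and the
floor is our choice where no rounding rule is standard. Clusters are
renumbered by population (ties: smallest member index) starting from 0.
Consensus scores are then recomputed inside each of the top 15 clusters
with the cluster's own size as *n*; a singleton cluster degenerates to
a single entry with S̄ = 1.

Because the tie rule references input positions, cluster partitions are
exactly permutation-invariant only when merge heights are tie-free;
with ties, two orderings can produce different (equally valid) cuts.

## Interface measures

* **Contacts**: the model's contact-map size at 5 Å.
* **Clashes**: inter-chain heavy-atom pairs at < 3 Å, counted as atom
  pairs. More than 25 clashes disqualifies a candidate.
* **Buried area**: Shrake–Rupley accessible surface with probe 1.4 Å,
  960 golden-spiral quadrature points per atom (both configurable),
  Bondi van-der-Waals radii shipped in code (unknown elements fall back
  to 1.70 Å with a warning). The interface area is
  (SASA(group1) + SASA(group2) − SASA(complex)) / 2 — the mean buried
  surface of the two partners, the convention matching published
  per-complex interface areas; the summed convention is available by
  flag. The implementation tests each atom's quadrature points once
  against all neighbors and once against same-group neighbors, which is
  algebraically identical to the three-call difference but threefold
  cheaper; the equality is verified in the test suite at elevated
  quadrature.

With 960 points, a single isolated sphere reproduces its closed-form
area to better than 0.1%, and buried areas are stable to ~1–2% under
rigid motion; quadrature error is the reason contact count precedes
area in the final ordering key (contacts are cutoff-exact).

## Selection logic

The candidate pool is the union of the consensus top 30 and the top 2
of each of the 15 most populated clusters (a model reached both ways is
pooled once and keeps both provenances). After clash exclusion, the
regime is decided by consensus sharpness:

* **Maxscore ≥ 0.1 (strong)** — all 10 submissions from consensus-ranked
  candidates;
* **Maxscore < 0.1 (weak)** — 1 candidate from the top of the consensus
  ranking plus 9 spread over distinct clusters in population order (one
  per cluster before any second picks).

Within the chosen quota, candidates are ordered by contact count, then
buried interface area, then consensus score — among comparably
consensual poses, the more extended interface is the better bet for a
high-accuracy model. The 0.1 threshold and the two quota patterns
codify what is, in expert practice, a judgment call; intermediate
blends are intentionally not invented. Both pool sizes, the threshold
and the quotas are configuration fields.

The pipeline is a pure function of (inputs, config): repeated runs are
byte-identical. Failures are tagged with the stage that raised them.

## Quality assessment

Against a reference structure, models are measured by:

* **f(nat)** — fraction of the reference's intermolecular residue
  contacts (5 Å) present in the model;
* **L-rms** — backbone (N, CA, C, O) RMSD of the ligand (smaller
  partner) after least-squares superposition of the receptor;
* **I-rms** — backbone RMSD over the reference's interface residues
  (any heavy atom within 10 Å of the partner) after their own
  superposition.

Classes are assigned best-first: high (f(nat) ≥ 0.5 and L-rms ≤ 1.0 or
I-rms ≤ 1.0), medium (≥ 0.3 and L ≤ 5.0 or I ≤ 2.0), acceptable (≥ 0.1
and L ≤ 10.0 or I ≤ 4.0), else incorrect — the standard CAPRI tiers
(Lensink et al. 2016, Proteins 84 Suppl 1, 323–348), shipped as an
editable table. The clash-penalty sub-rules of the full CAPRI protocol
are not implemented. For identical-sequence dimers both chain
assignments are evaluated and the better superposition kept.
Superpositions use `scipy.spatial.transform.Rotation.align_vectors`
(Kabsch); the test suite cross-checks against an independent SVD
implementation.

## Synthetic decoy generator

The generator emulates the structure of a blind-docking scoring set at
toy scale: a known complex, a fraction of near-native poses (predictors
that found the answer) and a remainder of incorrect poses, shuffled and
anonymized.

* **Reference**: each monomer is an idealized helical hairpin — two
  antiparallel helices (radius 2.3 Å, rise 1.5 Å/residue, twist 100°,
  backbone N/CA/C/O + CB, poly-alanine) with axes 9.5 Å apart. The
  second monomer docks along the hairpin-plane normal to a 3.2 Å
  surface gap, engaging both arms: 24 residue contacts, zero clashes,
  for the default 30-residue chains. A hairpin rather than a single
  helix is essential: a bare cylinder collapses random packings into a
  narrow family of side-by-side arrangements whose shared contacts
  mimic a false consensus.
* **Near-natives** (fraction *f*, default 0.3): chain B rigidly
  jittered, rotation σ = 2°, translation σ = 0.5 Å per axis — the scale
  at which poses remain high/medium quality, as several predictors
  converging on one template would produce.
* **Random decoys**: chain B uniformly rotated, approached from a
  uniform direction until touching, then pressed to a snug fit
  (allowing at most 10 mild clashes, well below the 25-clash exclusion
  level) so that incorrect poses bury a substantial patch, as real
  rigid-body decoys do; rejection-sampled to guarantee ≥ 1 contact, so
  every generated model survives filtering.
* **Swapped-monomer decoys** (optional): jittered poses of an
  alternative reference whose chain A is a straight helix — a different
  monomer fold presenting a different interface, emulating ensembles
  whose predictors disagree about the monomer itself.
* **Clash-injected decoys** (optional): near-native poses pushed into
  overlap until they exceed the clash threshold, for exercising the
  exclusion rule.

One RNG stream (`numpy` PCG64, seeded from the spec) drives all
randomness including the file-name shuffle. Ground truth (labels and
the reference contact set) is returned and optionally written as JSON
beside the PDB files and target FASTA.

Under these defaults, 100-model ensembles give Maxscore ≈ 0.31 at
*f* = 0.3 and ≈ 0.07 at *f* = 0 (below the 0.1 trigger), with Maxscore
strictly increasing in *f* — the synthetic analogue of the
sharpness-vs-enrichment relation the selection logic relies on.

### What passing tests do and do not show

The generator's decoys are rigid, idealized, poly-alanine, and
single-interface; they have no side-chain packing, no flexible
backbones, no energy-correlated decoy structure, and their interfaces
are far smaller than real protein interfaces (tens, not hundreds, of
contacts). Tests passing on them validate the *bookkeeping and the
consensus mathematics* — filtering, renumbering, symmetrization,
scoring, clustering, quota logic, geometry — under controlled truth.
They do not demonstrate scoring performance on real ensembles, where
enrichment, decoy correlations and interface sizes differ; a random
pose can also legitimately land near the native groove and earn an
honest "acceptable", so generator labels and quality classes are
correlated, not identical.

## Numerical and scale choices

* Contact/clash detection uses exact k-d-tree neighbor queries with
  strict re-filtering at the cutoff; no approximations.
* The agglomeration recomputes an O(n²) minimum per merge (O(n³)
  overall, vectorized); it is comfortable to a few thousand models,
  which covers real scoring-set sizes.
* Test and acceptance runs use 100-model ensembles of 30-residue
  chains — large enough for stable consensus statistics and ≥ 9
  clusters at *t* = n/10, small enough that the full pipeline runs in
  seconds.
* Degenerate inputs: fewer than 2 models → consensus undefined (error);
  zero-contact maps are rejected at scoring (they are filtered
  upstream); singleton clusters rank trivially at S̄ = 1; if fewer than
  10 clash-free candidates survive, all survivors are returned with a
  warning.

## Known limitations

* No mmCIF input, nucleic-acid chains, or multi-model PDB files.
* One designated chain-pair partition per run; multiple distinct
  interfaces of higher-order oligomers must be scored as separate runs.
* The buried-area convention (mean vs. sum) cannot be inferred from a
  single number; both are offered, mean is the default.
* Interface-extent re-ranking assumes the candidate pool is already
  enriched in correct poses; in a weakly consensual pool it can promote
  an extended incorrect pose. This is intrinsic to the method, not an
  implementation artifact.
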