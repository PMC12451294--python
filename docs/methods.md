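# Methods

This note records the model, the defaults, and the design choices behind
them, in the package's own terms. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Pharmacophores, pockets, features

A pharmacophore center is a 3D position plus one of six feature classes —
HydrogenAcceptor, HydrogenDonor, Hydrophobic, Aromatic, NegativeIon,
PositiveIon — in that canonical one-hot order. Coordinates are Angstrom in
the source-file frame; I/O never recenters.

Ligand-side detection (`featurize.detect_ligand_features`) uses structural
rules on an RDKit-perceived molecule: donors are N/O bearing a hydrogen
(explicit or implicit, inferred from valence); acceptors are N/O with an
available lone pair and no positive charge (aromatic N–H excluded);
aromatic features sit at centroids of 5/6-membered aromatic rings;
hydrophobic features at centroids of connected clusters of ≥3 non-aromatic
carbons with no heteroatom contact; charged features come from formal
charges and carboxylate/sulfate/phosphate and amidine/guanidine groups
(group centroids). Aromatic carbons are deliberately excluded from
hydrophobic clustering so a phenyl ring yields one aromatic feature rather
than an aromatic plus a coincident hydrophobic; this keeps the synthetic
ground truth unambiguous.

Pocket-side detection is residue-based: backbone N–H donor and C=O
acceptor, plus side-chain rules (Asp/Glu carboxylate → NegativeIon,
Lys/Arg/His → PositiveIon, Phe/Tyr/Trp/His rings → Aromatic, aliphatic side
chains → Hydrophobic, Ser/Thr/Tyr hydroxyls → donor+acceptor, Asn/Gln
amides → acceptor+donor). Unknown residues contribute nothing; partial
residues contribute only features whose atoms are all present.

### Complementarity thresholds

One table drives both training extraction and the validity metric, so the
two cannot drift apart: donor↔acceptor 4.0 Å; hydrophobic↔hydrophobic,
aromatic↔aromatic, aromatic↔positive (cation–π) and ionic pairs 5.0 Å.
These are standard interaction-geometry ranges; they are configurable
(`ComplementarityRule`), and `validity` is by construction monotone
non-increasing as thresholds shrink.

An interaction pharmacophore keeps each ligand feature with a
complementary pocket feature within its threshold. Training augmentation
subsamples 3–8 centers uniformly (size uniform on [3, min(8, N)], subset
uniform without replacement); pharmacophores with fewer than 3 centers are
excluded.

## Graph construction

Protein nodes are the union over centers of each center's k nearest pocket
atoms (k = 8 default; the atom-type vocabulary is {C, N, O, S, P, F, Cl,
Br, I, other}). Pharm–pharm edges are complete; pharm–protein edges
connect each center to its k nearest retained atoms; protein–protein edges
connect retained atoms within 4.5 Å. Edges are stored directed-symmetric.
Translation is handled by the frame, not the network: `center_frame` moves
the retained-protein centroid to the origin and records the exact offset.

## Diffusion

`make_schedule(T, power=2, clip=1e-7)` sets α_t² = clip + (1 − 2·clip)·(1 −
(t/T)^power)², σ_t² = 1 − α_t², so the variance-preserving identity holds
to machine precision, α_0 ≈ 1 and α_T ≈ 3e-4. Noising applies z_t = α_t z_0
+ σ_t ε with independent standard Gaussian components to coordinates and
features alike; one-hot features are scaled by 0.25 before noising
(standard for categorical channels in this model family) and unscaled
before the final argmax. Only pharmacophore nodes are noised — protein
nodes are clean conditioning context. The diffusion acts on
pocket-centroid-relative coordinates so its unit-Gaussian endpoint sits at
the pocket center regardless of the crystal frame.

## The denoiser

Message passing over the heterogeneous graph with scalar node channels
(width 64, 4 layers by default): edge messages combine projected source and
target embeddings with 16 Gaussian radial basis functions of the edge
distance (cutoff 10 Å); node updates are residual. The time step enters as
t/T plus a 4-frequency sinusoidal embedding on pharmacophore nodes.

Equivariance is structural, not learned: the coordinate head emits, per
pharmacophore node, a sum over incoming edges of learned scalar weights (16
vector channels, linearly combined) times the fixed edge difference vectors
(x_dst − x_src)/(d + 1). Distances and difference vectors are constants of
each forward pass, so coordinate outputs rotate exactly with the inputs and
feature outputs are exactly invariant — the test suite measures deviations
at machine precision. Because protein neighbors anchor the frame, the
vector head can express arbitrary (not merely centroid-free) noise
estimates.

The default activation is leaky-ReLU (slope 0.1); SiLU is available via
config. The choice is a CPU-throughput one — the network is trained by a
small reverse-mode autodiff engine over float64 numpy arrays
(`autodiff.py`, finite-difference-checked in the tests), and removing
transcendental activations nearly halves the per-step cost without
affecting the equivariance structure.

Training draws t uniformly from [1, T] per sample, builds the graph from
the *noised* center positions (matching what the sampler sees), and
minimizes the mean squared error over all coordinate and feature
components with Adam (β defaults, global-norm gradient clipping at 1.0).
A single integer seed fans out to parameter initialization, noise draws
and shuffling through named substreams. Checkpoints (npz with an embedded
config record) reload bit-exactly.

## Sampling

Generation initializes n centers at Gaussian(pocket centroid, 2 Å) with
standard-Gaussian feature vectors, then runs the variance-preserving
ancestral update from t = T to 0 (T = 1000 default; the toy configuration
uses 200), with the final step noise-free and feature types decoded by
argmax only at the end.

Two numerical choices matter:

* **Clean-state clamping.** The ancestral mean can be written in terms of
  the implied clean state x̂₀ = (z_t − σ_t ε̂)/α_t, and near t = T the
  1/α_t factor amplifies any noise-prediction error enormously (α_T ≤
  1e-3). x̂₀ is therefore clipped to a ball of radius max‖pocket‖ + 2 Å
  about the pocket center (centers live inside pockets), and feature
  estimates to a fixed range. Without the clamp an imperfectly trained
  model diverges in the first few steps; with it the state contracts onto
  the data manifold as predictions sharpen at lower t.

* **Pathwise equivariance.** Coordinate noise is drawn in a
  pocket-canonical frame (principal axes of the pocket atoms, ordered by
  variance, signs fixed by third moments, right-handed). Rotating the
  pocket rotates that frame covariantly, so the same seed yields the
  exactly rotated trajectory — equivariance holds per sample, not only in
  distribution. Near-spherically symmetric pockets would make the frame
  ill-conditioned; the synthetic pockets are deliberately anisotropic.

Graph topology is rebuilt from the current positions at every step by
default (consistent with how training wires graphs from noised positions);
a fixed-topology mode exists in config. No validity filtering happens
during sampling — validity is a reported metric, never a sampler
constraint.

## Matching and metrics

A molecule matches a query when some injective, type-consistent assignment
of its conformer features to **all** query centers admits a rigid
(proper-rotation) least-squares superposition with RMSD ≤ 1 Å — the
tolerance matches the 1 Å default center radius. The search enumerates
assignments by backtracking with dynamic pairwise-distance pruning: a
pairwise deviation D certifies RMSD ≥ D/(2√n), so pruning against the best
RMSD found so far is lossless and the search returns the exact minimum
(the tests verify equality with unpruned exhaustive enumeration plus an
independent superposition routine). Conformers are inputs; one best
conformer is reported per molecule.

EF = (active fraction among hits)/(active fraction in database); a
zero-hit query has undefined EF and is excluded from aggregation, while
precision is defined as 0 there so F1 = 0. A query-size filter keeps
queries with at most a configurable number of hits (conventionally 1% of
the database) to drop unspecific pharmacophores. Strain energy is the UFF
energy of the input geometry minus the energy after local minimization
(RDKit UFF, 2000 iterations default); an optional receptor-exclusion
post-filter (off by default) drops hits whose aligned features fall within
1.5 Å of a pocket heavy atom.

## Synthetic study conditions

The fixture pocket plants one complementary site of each of the six types
at octahedral positions with per-site radii 5.4–6.9 Å (distinct radii and a
random anisotropic carbon shell of 48 inert atoms keep the geometry
generic), built from minimal residues co-designed with the pocket detector
so planted and detected features agree to 1e-9 Å. Training pairs place 3–8
complementary ligand-side centers at sites plus Gaussian jitter (0.2 Å
default; validity is exactly 1 at zero jitter). The screening library (20
actives, 180 decoys, 3 conformers each by default) embeds the truth
pharmacophore into one conformer per active within 0.3 Å using molecular
fragments whose detected feature lands at the requested point (benzene for
aromatic, methanol oxygen for donor, ether oxygen for acceptor, propane for
hydrophobic, methylammonium for positive, acetate for negative), plus
distractor fragments; decoys scale the truth geometry radially by 2.2,
which moves every pairwise distance far beyond what any RMSD ≤ 1 Å
alignment of ≥2 centers can absorb, so decoys provably cannot match.

The toy training condition used by the tests and the acceptance script is
2000 pairs, T = 200, 20 epochs, batch 24, lr 1e-3 — sized for minutes on a
single CPU; the full-scale defaults (T = 1000, lr 1e-4, 80 epochs) remain
the package defaults.

What passing on these fixtures shows — and what it does not: the pipeline
learns genuine geometry (sites are recovered only through protein-atom
context, and element patterns distinguish site types), but the fixtures
have rigid, noise-free pockets, idealized fragment chemistry, one pocket
per training set, and planted features that the detector finds exactly.
Real pockets bring conformational variability, ambiguous protonation,
detector noise and vastly more diverse chemistry; results here bound the
machinery, not real-screen performance.

## Known limitations

* Feature directionality (donor/acceptor/aromatic vectors) is not modeled.
* Pharmacophore size is user-specified, not model-determined.
* The matcher is exact but exhaustive-by-design; it is meant for desk-scale
  queries (≤8 centers), not indexed database search.
* External docking/minimization scores are consumed only as optional CSVs;
  no docking is performed.
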