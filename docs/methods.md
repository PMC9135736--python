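# Methods

## Input representation

Each residue with a complete (N, CA, C) backbone receives a local
orthonormal frame: Gram-Schmidt on (C−CA, N−CA) with the cross product as
the third axis, origin at the CA. Residues missing backbone atoms are
excluded from the graph. All geometric features are expressed in these
frames, which makes the representation exactly invariant under global
rigid motions (measured deviations are at machine precision, the tests
enforce ≤ 1e-5).

Node features (46-dim): a 21-class amino-acid one-hot (20 canonical + UNK
for non-canonical residues; waters and hetero ligands are never loaded),
sin/cos of the backbone torsions φ, ψ, ω, the unit vector from the CA to
the side-chain heavy-atom centroid in the local frame (zero for glycine),
and a radial-basis encoding of the CA-centroid distance. Undefined
dihedrals — chain termini, residues flanking a chain break (consecutive
CA-CA above 4.5 Å), degenerate collinear geometry — are encoded as
(0, 0) rather than with a sentinel angle, keeping all features bounded.
Chain breaks suppress dihedrals but not graph edges.

Edge features (88-dim), for each of the k nearest neighbors by CA-CA
distance: an RBF encoding of the distance (16 Gaussian centers uniform on
[0, 20] Å, width equal to the spacing; the side-chain distance reuses the
encoder with centers on [0, 8] Å), the unit direction to the neighbor CA
in the source frame, the unit quaternion of the relative rotation between
the two frames (Shepperd's method, sign fixed to a non-negative scalar
part to resolve the double cover), and a one-hot of the sequence offset
clipped to ±32 (65-dim). k = 30 by default and configurable; distance
ties are broken toward the lower residue index, with distances compared
at a 1e-9 tolerance so that neighbor order is stable under rigid motions.
The k, RBF grid and relative-position width are package choices — they are
conventional values for residue-graph encoders, not externally fixed
constants.

## Network

Post-norm Transformer wiring throughout: each sub-layer is wrapped as
x ← LayerNorm(x + Dropout(Sublayer(x))). One block applies protein
context attention (graph attention in struct mode: keys and values are
linear maps of the concatenated neighbor embedding and edge features;
ordinary self-attention in seq mode), peptide self-attention, reciprocal
cross-attention updating both streams from one shared Q·Kᵀ product, and a
d_model → d_i → d_model feed-forward on each stream. Every head uses the
full d_k/d_v and the concatenated heads are projected back to d_model.
The peptide stream (and the protein stream in seq mode) adds sinusoidal
positional encodings; the structural stream relies on the relative-position
edge features instead. The output head is a two-class softmax, pairing
naturally with the weighted cross-entropy loss. Weights are
Xavier-uniform, fully seeded. Defaults: d_model = d_i = d_k = 64,
d_v = 128, 6 heads, 6 blocks, dropout 0.2 after each attention layer.

The whole network (and its training) runs on a small reverse-mode
automatic-differentiation engine over NumPy arrays (`pepsite.autodiff`),
whose primitive gradients are verified against central differences in the
test suite.

## Dataset construction

Peptide complexes: keep a record iff the crystal resolution is 2.5 Å or
better (the crystallographic reading of "at least 2.5 Å"), the receptor
chain exceeds 30 residues, the partner has at most 25, and the buried
surface area is at least 400 Å². Records without a reported resolution
are excluded with a logged reason; the rules are evaluated independently
so the surviving set is order-free. Binding residues are receptor
residues with any heavy atom within 6 Å of any partner heavy atom,
computed against the full partner chain.

Solvent-accessible surface area is an in-repo Shrake-Rupley: golden-spiral
sphere sampling (960 points per atom by default, deterministic), standard
heavy-atom van der Waals radii, 1.4 Å probe, unknown elements defaulting
to 1.8 Å with a warning. BSA uses the unhalved two-body formula
SASA(A) + SASA(B) − SASA(A∪B) over heavy atoms; whether to halve the
interface or include hydrogens was an open convention and this choice is
recorded here.

Sequence identity is computed from a global alignment (match 2, mismatch
−1, gap open −10, extend −0.5): identity = matches / aligned columns
(both-residue columns only), coverage = aligned columns / shorter length.
The stiff gap opening matters: with permissive gaps, alignments of
unrelated sequences fragment into match-enriched islands and this identity
definition saturates near 50%. These conventions differ slightly from
dedicated clustering tools and are configurable. Redundancy is handled by
longest-first greedy centroid clustering at 30% identity (a built-in
stand-in for an external clustering tool), cluster-level seeded 90/10
train/validation splitting (no cluster ever spans splits), and
independent-test hygiene: drop test sequences over 30% identity at ≥ 70%
coverage to any reference, cluster survivors at 90%, keep centroids.

Fragment ("hot segment") complexes for pre-training scan every contiguous
5-25-residue window of a partner chain against a ≥ 50-residue receptor.
The window's interface score is −(heavy-atom contact pairs under 5 Å) —
a deliberately simple contact count whose sign mimics an interface
energy. It is NOT equivalent to a physics-based interface energy; only
the filtering logic around it is faithful: keep windows scoring at most
one standard deviation above the mean of the real peptide-complex score
distribution, then re-apply the 400 Å² BSA filter.

## Training

Adam, one complex per iteration, fully seeded. Loss: class-weighted
cross-entropy with inverse-frequency weights normalized to mean one
(binding residues are the minority class); during fine-tuning each example
is additionally weighted by the inverse of its sequence-cluster size.
Pre-training does not use example weights — the cluster weighting is a
fine-tuning device. Learning rates 1e-4 (struct pre-train/fine-tune) and
1e-5 (seq fine-tune); iteration caps 150,000 (pre-train) and 35,000
(fine-tune). Early stopping monitors the validation loss every 50
iterations (desk-scale cadence; patience 10 evaluations) and restores the
best-validation checkpoint. Checkpoints refuse to load across input modes
or mismatched shapes.

## Peptide-agnostic scoring

A trained model queried with a poly-glycine probe (length 10 by default; a
seeded random length in [5, 25] is available via `--probe-len randint:5:25`)
yields probabilities p_r. The site score maximizes
α·mean(top-n p_r) + (1−α)·pdf(n/N) over n = 1..N, ties to the smaller n,
where the pdf is a Gaussian fitted (sample mean/SD) to per-protein
binding-residue fractions of the training set — fractions, not
percentages; the prior is evaluated as-is without renormalizing to the
unit interval. α defaults to the published operating points 0.955
(struct) and 0.965 (seq) and can be re-calibrated by grid search
(step 0.005) maximizing the Pearson correlation — Spearman by flag —
between scores and per-protein MCC on a validation set; correlation ties
resolve to the smaller α.

## Evaluation

ROC AUC (ties counted one half), MCC from the 2×2 table with any zero
marginal mapping to 0, and top-k hit (k = 10; probability ties broken by
lower residue index). The MCC binarization threshold is 0.5 on the
binding-class probability and exposed as a flag. Superpositions use a
reflection-free Kabsch fit (SVD with determinant sign correction); a
peptide is annotated as undergoing a conformational change when its
Cα-RMSD to any same-length reference conformation is at least 2.5 Å
(inclusive boundary).

## Synthetic study conditions

The fixture generator builds ideal α-helices from internal coordinates
(φ = −57°, ψ = −47°, ω = 180°; standard bond lengths/angles; a CB-like
carbon on non-glycine residues). A complex places a peptide helix
(16 residues by default) against a seeded receptor contact patch (8-12
contiguous residues near the chain center) aligned with the receptor
axis: binders are slid to a 2.8 Å minimum heavy-atom separation and then
inward as needed (never below 2.0 Å) until the buried surface area
exceeds 400 Å²; decoys are held beyond 8 Å. The tight approach distance
compensates for the sparse synthetic side chains, which bury far less
area per contact than real rotamers. Binder receptors carry a learnable
intrinsic signal — patch residues are drawn from a hydrophobic alphabet,
everything else from a polar one — emulating the hydrophobic hot-spot
composition of real peptide-binding sites; this is what makes
peptide-agnostic discrimination of binders from decoys possible from the
receptor alone. The fixtures are deliberately unrealistic in every other
respect (no rotamers, no packing, no energetics), so passing tests
demonstrate correctness of the machinery and learnability of planted
signal, not performance on real complexes.

Desk-scale experiments use a reduced model (2 blocks, d_model 32, 2
heads, k = 8, dropout 0.1) trained for 500 iterations at learning rate
1e-3 — an overfit-capability setting chosen so the toy run finishes in
seconds on one CPU; the published rates and caps above apply to
full-scale training, which this package supports mechanically but which
requires PDB-scale data and pretrained language-model weights.

## Known limitations

- The language-model embedder ships as a deterministic mock (32-dim) and
  an optional real-transformer adapter; the adapter needs optional
  dependencies and downloaded weights and is never exercised in tests.
- The fragment interface score is a contact count, not an energy;
  absolute score distributions are not comparable to energy-based ones.
- Greedy identity clustering approximates, but does not reproduce,
  dedicated clustering tools; identity/coverage conventions are documented
  above and configurable.
- Benchmark-scale numbers (published test-set AUCs, proteome scans) are
  out of desk-scale reach by design; nothing in this package claims them.
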