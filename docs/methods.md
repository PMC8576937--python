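# Methods

This note records the modelling choices behind `affinity-attn`: what is
computed, which parameters matter, what the synthetic generators do and do
not emulate, and where the design was genuinely open.

## Contact descriptors

A complex is reduced to its intermolecular contacts: every pair of one
ligand and one protein heavy atom within 12 Å (Euclidean). Only the nine
heavy-atom types C, N, O, F, P, S, Cl, Br, I participate; atoms of other
elements (metals, selenium in selenomethionine, boron/silicon ligands) are
retained in the structure but are invisible to contact, descriptor and
interaction-term computations. Each contact is extended by the one-bond
neighborhoods of its two atoms, keeping bond kinds (single, double, triple,
amide, aromatic) but discarding atom identities and neighbor order.

The canonical serialization is
`L:<elem>[<bond>:<elem>,...]|P:<elem>[<bond>:<elem>,...]` with neighbor
lists sorted by (element rank in the nine-type order, bond rank
s < d < t < am < ar). Because the sort key is a total order on neighbor
entries, canonical strings are invariant under any relabeling of atoms or
reordering of bonds by construction; the test suite additionally verifies
this behaviorally under random permutations and rigid motions. Multiple
contacts mapping to the same canonical string increment one frequency.

Contacts are found with a k-d tree but specified — and tested — against an
all-pairs brute-force scan. Descriptor selection fits a random-forest
regressor (500 trees, fixed seed) on the count matrix and keeps the top-u
features by impurity importance, ties broken by vocabulary position; the
reference u is 2500.

## Protein bond perception

Descriptor extension needs covalent bonds, which PDB files do not carry.
Protein connectivity comes from residue templates for the 20 standard amino
acids with *localized* (Kekulized) bond orders following the PDB chemical
component dictionary: alternating single/double bonds in HIS/PHE/TYR/TRP
rings, a double backbone carbonyl, amide-kind side-chain C–N bonds in
ASN/GLN. Inter-residue peptide C–N bonds (C–N distance ≤ 1.8 Å between
consecutive residues) are typed amide; SG–SG pairs within 2.3 Å become
disulfide single bonds. Kekulized typing means a protein ring carbon
presents one single- and one double-bonded carbon neighbor, which is also
how the descriptor notation distinguishes such centers. The aromatic bond
kind therefore only arises from ligand input files, whose bond records
(MOL2 codes 1/2/3/am/ar, SDF orders) are trusted as written. A ligand file
without bond records is rejected outright.

Preprocessing removes hydrogens, waters (HOH/WAT) and every HETATM group
other than the named ligand (cofactors). Non-standard residues keep their
atoms but get no template bonds.

## Vina-style interaction terms

The six auxiliary features follow the AutoDock Vina functional forms on the
surface distance d = r − R_i − R_j, with radii (Å) C 1.9, N 1.8, O 1.7,
F 1.5, P 2.1, S 2.0, Cl 1.8, Br 2.0, I 2.2 and an 8 Å interaction cutoff on
r:

| term | form |
|---|---|
| gauss1 | exp(−(d/0.5)²) |
| gauss2 | exp(−((d−3)/2)²) |
| repulsion | d² for d < 0, else 0 |
| hydrophobic | linear 1→0 on d ∈ [0.5, 1.5], clamped; carbon–carbon pairs where both carbons bond only to carbon |
| hbond | linear 1→0 on d ∈ [−0.7, 0], clamped; donor–acceptor pairs |

Donors are nitrogens with free valence (implicit hydrogens inferred from
nominal bond orders, since structures are hydrogen-stripped); acceptors are
any N or O. This heuristic misses pyrrole-type N–H donors and treats all
N/O as acceptors; it is deliberately simple and lives in one table so it
can be swapped. The sixth feature counts active rotatable ligand bonds:
acyclic, non-terminal single bonds that are not amides.

## Network

For a count vector d of length u and embedding matrix E ∈ ℝ^{u×h}
(initialized from the standard normal truncated at |z| ≤ 2):

1. row scaling E′ᵢ = (wᵢ dᵢ) Eᵢ with a learnable per-descriptor frequency
   weight wᵢ (init 1);
2. a shared dense layer maps each of the h columns (length u) to
   `column_dense_out` values; the matrix is flattened row-major into one
   single-channel sequence of length `column_dense_out · h`;
3. five convolution branches (windows 2, 4, 6, 8, 10; four layers with
   3, 6, 6, 9 filters; ELU; max-pool 2/2 after each layer) read the
   sequence; their flattened outputs concatenate with the six standardized
   Vina terms and encode to e (ELU dense);
4. attention: q = dense(e), keys = values kᵢ = dense(Eᵢ) from the *raw*
   embedding rows, weights = softmax(q·kᵢ) (max-subtracted for stability),
   context = Σ weightsᵢ kᵢ, encoded to c;
5. [e; c] → 512–256–128 ELU feed-forward head → predicted pK.

The reference geometry `column_dense_out = 5, h = 53` makes the conv input
265 long so the five branch outputs flatten to 15, 13, 11, 10, 8 windows of
9 filters — exactly 513 values, which a test pins. Ablation flags drop the
Vina fusion and/or replace the attention head with an e-only head, giving
the four variants D, D+A, D+V, D+V+A.

Training minimizes MSE + λ‖W‖² (λ = 1e-4 over weight matrices, biases
excluded) with Adam at learning rate 0.005 and batch size 256, up to 120
epochs with early stopping on validation MSE (patience 20) and best-weights
restoration. The six Vina inputs are standardized with training-set
mean/variance stored in the checkpoint — their raw scales differ by orders
of magnitude (a gauss2 sum vs. a rotatable-bond count) and unstandardized
they stall optimization at this learning rate. Dense and convolution
kernels use Glorot-uniform init; the whole network runs on an in-package
reverse-mode NumPy autodiff engine in single precision (float64 is used for
the numerical gradient checks that pin the engine's correctness).
Checkpoints are a zip of the parameter arrays plus the config as JSON.

## Evaluation

`regression_metrics` yields MAE, RMSE, Pearson, Spearman (average-rank
ties), and SD — the root-mean-square residual of the true affinities about
the least-squares line of truth on prediction, with N−1 denominator (the
CASF convention). `average_rank` ranks models within each dataset (1 best,
ties averaged) and means across datasets.

Protein structure similarity shells out to TM-align on every chain pair of
the two proteins and returns the lowest (or highest) pairwise-chains
TM-score; of the two normalizations TM-align prints, the one by the shorter
chain is used. A missing executable raises an explicit error with an
install hint. Ligand similarity is the Tanimoto coefficient over 2048-bit
Morgan radius-2 fingerprint bit sets (recorded in output metadata; both
empty ⇒ 0). Generalization splits keep test complexes whose maximum
similarity to the training set is below a caller-supplied threshold — there
is deliberately no default threshold.

Dataset manifests apply the refined-set conditions (resolution ≤ 2.5 Å,
Kd/Ki with pK in the inclusive range [2, 12], non-covalent, nine-element
ligands) and overlap removal by PDB ID: v2016 refined minus the CASF lists
gives training, v2018 refined minus (training ∪ CASF) validation, and the
CSAR sets minus everything, re-filtered, the external tests. Covalency and
ligand-element annotations are taken from index-file side tables, not
re-derived from geometry.

## Synthetic data

`make_two_contact_fixture` builds a deterministic complex with exactly two
contacts: two separated fragment pairs placed collinearly 11.5 Å apart with
neighbors pointing away, every other cross-distance above 12.6 Å, so the
contact count is robust to floating-point noise. The protein fragments are
truncated real residues (a GLY backbone carbonyl and a PHE ring carbon with
its two ring neighbors), so writing the fixture to PDB and reloading it
reproduces the same bonds through template perception.

`generate_complex` builds random tree-bonded fragments (nine-element
ligands, protein pockets) and places the ligand along one axis so that the
closest surface gap falls from 12.5 Å (contact density 0, provably zero
contacts at the 12 Å cutoff) to 2 Å (density 1). `generate_dataset` draws
descriptor counts from a Poisson mixture whose per-descriptor rates are a
fixed property of the vocabulary size — so differently-seeded draws are
samples from one population and can serve as train/validation/test splits —
and plants a linear affinity signal: five descriptors with mixed-sign
effects of 0.35–0.6 pK per count, a 0.05 pK-per-unit gauss1 contribution,
and Gaussian noise of 0.3 pK by default. An ordinary-least-squares fit
recovers the planted weights within 10% before the network ever sees the
data, guarding against generator bugs.

What the generators do *not* emulate: physically valid geometry or
chemistry (no sterics, no force field, bond kinds drawn at random), realistic
descriptor sparsity (real complexes activate a few hundred of thousands of
descriptors), affinity structure beyond a linear signal, and any
protein-family or ligand-series redundancy. Passing the recovery study
therefore demonstrates that the implementation can learn and attend to a
known signal under controlled conditions — not that it reproduces benchmark
accuracy on real complexes, which requires the licensed structural datasets.

## Study sizes

The planted-signal study uses u = 50 descriptors, 2000 training / 400
validation / 400 test complexes and noise 0.3 pK. The held-out-correlation
run trains for 25 epochs; the attention-enrichment study trains 20
independently seeded models for 12 epochs each and compares the mean number
of signal descriptors inside each complex's top-10% attention set against
the uniform (hypergeometric) null by Monte-Carlo permutation. These sizes
were chosen as the smallest at which the linear signal is comfortably
identifiable (the OLS check above) while keeping a full study in the
minutes range on one CPU core.

## Known limitations

- Attention weights saturate (the softmax often concentrates on one
  descriptor per complex) because the dot products are unscaled; the
  enrichment analysis works on the induced ranking, and per-complex weight
  vectors should be read as rankings rather than calibrated probabilities.
- Donor/acceptor and hydrophobic typing are heuristics on hydrogen-stripped
  structures; protonation states are out of scope.
- Protein bonds come from templates: modified residues and metal
  coordination are not perceived.
- TM-align is wrapped, not reimplemented; protein-similarity computations
  require it on PATH.
- Training reproducibility is bitwise for initialization; training itself
  is deterministic up to BLAS reduction order in single precision.
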