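# Methods

`ugtshape` implements a latent-space workflow for asking a structural
question about enzyme–substrate specificity: *do the conformations an enzyme
samples at its substrate interface depend on which substrate is bound?* The
workflow was designed around plant UDP-dependent glycosyltransferases
(UGTs), whose GT-B fold binds UDP-activated sugar donors in a cleft lined by
a small set of interface residues, but nothing in the code is specific to
that family beyond the bundled interface residue lists.

## Pipeline model

Each (variant, substrate) condition is a conformational ensemble of Cα
coordinates — in practice frames drawn from molecular dynamics, here read
from multi-model PDB or plain TSV trajectories. The analysis proceeds:

1. **Contact featurization.** A frame is reduced to a binary symmetric
   matrix over an interface residue selection: entry (i, j) is 1 iff the
   Cα–Cα distance is ≤ 8 Å. The cutoff is inclusive, and the diagonal is 1
   by literal application of the rule (self-distance 0 ≤ 8 Å); a constant
   diagonal carries no information and is harmless to the autoencoder.
   Contacts are binary, not distance-weighted: the contact definition is
   categorical.
2. **Size equalisation.** Selections differ in size across variants (the
   bundled UGT interface lists expand to 21, 22, 22, 22 and 21 residues).
   Smaller matrices are padded by appending trailing zero rows/columns up to
   the corpus maximum (21 → 22, giving a uniform 22×22 corpus). Trailing
   (bottom/right) placement keeps the residue→row mapping of the real block
   stable; appending exactly one row and one column is the only padding
   reading consistent with a 21 → 22 transformation.
3. **Merge and split.** Matrices from all conditions are merged and split
   80/20 into training/validation with a single seeded uniform draw over
   the merged corpus (not stratified per condition; merge-then-split order).
   |train| = round(0.8·n), round-half-up. The split exists only for the
   convergence check — latent projections are computed for the full corpus,
   because ensemble profiles are read from whole ensembles.
4. **CVAE.** The encoder is three 3×3 convolutions with strides 1, 2, 1 and
   a fully connected layer producing a diagonal-Gaussian posterior; the
   decoder mirrors it (fully connected, three transposed convolutions with
   the stride pattern reversed) with Bernoulli-logit output, a standard
   symmetric choice where only the encoder shape is prescribed. The loss is
   element-wise binary cross-entropy plus an unweighted KL term (plain VAE
   objective, appropriate for binary matrices), optimised with RMSProp at
   learning rate 0.001 (other RMSProp constants at the common ρ = 0.9,
   ε = 1e-8).
5. **Latent analysis.** Frames are embedded at the posterior mean (no
   sampling), projected to 2D with t-SNE for visualization, and cluster
   separation of substrate- or variant-labelled groups is quantified by
   silhouette.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| contact cutoff | 8.0 | Å | standard Cα contact radius; inclusive |
| split ratio | 0.8 | – | 80/20 train/validation |
| conv filters | 16/16/16 | – | small enough for CPU desk-scale training |
| latent dim | 3 | – | smallest space that separates multi-state mixtures with headroom |
| learning rate | 0.001 | – | RMSProp step size |
| batch size | 64 | – | stable gradient estimates at these corpus sizes |
| convergence | rel. Δ < 1e-3 for 10 epochs | – | operationalises "train until both losses converge" |
| max epochs | 200 | – | hard cap for the convergence loop |
| t-SNE perplexity / iters | 30 / 1000 | – | library-standard, PCA init, seeded |
| separation threshold | 0.25 | silhouette | midway between the overlapping (≈0) and separated (≳0.5) pilot regimes |
| census cutoff | 5.0 | Å | side-chain proximity radius for the donor site |
| MSA coverage / identity | 0.75 / 0.90 | – | hhfilter-style defaults |

Silhouette is always computed on the latent codes, never on the t-SNE map:
t-SNE distances are not metrically meaningful, so the 2D projection is for
figures only. A label pair is "separated" when its two-group silhouette
meets the threshold. "Representative structure" of a group is
operationalised as the frame whose latent code is nearest to the group
centroid (Euclidean), ties broken to the lowest frame index; no such
definition is standard, and this one is deterministic and
permutation-invariant.

The CVAE is implemented as a self-contained numpy network (im2col-based
convolutions with hand-written adjoints, verified against central finite
differences in the test suite). The network runs in float32 with float64
loss accumulation; all randomness — weight initialisation, minibatch
shuffling, posterior sampling — comes from one config seed, so training is
bit-reproducible on a given machine. Validation loss is evaluated at the
posterior mean, making it deterministic given the weights. Non-finite
losses abort training with the failing epoch; log-variances are clipped to
[−10, 10] to keep exponentials in range.

## Synthetic ensembles and alignments

The generator emulates exactly what downstream stages consume, with planted
ground truth:

* **Ensembles** are i.i.d. mixtures of "metastable states": each frame
  picks a state by its occupancy, takes that state's anchor Cα coordinates
  (an idealised α-helical trace, optionally with a rigidly displaced loop
  block), and adds isotropic Gaussian noise. A ~12 Å block displacement
  toggles every contact between the block and its former neighbours
  robustly at 1 Å noise (distance fluctuations ≈ 2 Å). Hidden per-frame
  state labels ride along for test oracles and are never read by pipeline
  stages.
* **Two ready-made study scenarios** bracket the qualitative outcomes the
  method is meant to distinguish. In the *shared-state* scenario every
  substrate samples the same closed/open state pair at 50/50 occupancy, so
  substrate-labelled latent clusters must overlap (silhouette ≈ 0). In the
  *substrate-specific* scenario each substrate locks its own displaced-block
  conformation, so clusters must separate. Default conditions: 2 substrates
  × 1000 frames, 21 pseudo-residues, 1 Å noise.
* **Alignments** draw residues uniformly per column; a planted covarying
  pair (i, j, coupling) rewrites column j as a fixed cyclic permutation of
  column i with probability equal to the coupling; gaps are inserted i.i.d.
  last.

What the generator does *not* emulate: Markov kinetics between states
(sampling is i.i.d. per frame — latent clustering needs only the marginal
state structure), side chains (featurization reads only Cα positions),
anisotropic or correlated coordinate noise, phylogenetic correlation
between alignment rows, and realistic amino-acid composition. Passing tests
therefore demonstrate that the pipeline recovers planted marginal structure
under isotropic noise, not that it resolves subtle conformational biases in
real MD data.

## Binding-site census and divergence

The census lists residues whose side-chain heavy atoms (atom name outside
{N, CA, C, O, OXT}; hydrogens excluded) come within 5 Å of any ligand atom.
Glycine, having no side-chain heavy atoms, never qualifies. The census is
monotone in the cutoff by construction.

For mutant design, each census residue of a reference variant is mapped to
its alignment column by cumulative non-gap counting over the reference row
(the alignment must use the structure's sequence; residue identities are
cross-checked and mismatches are errors). A column is *conserved* when all
variants are identical. A single *divergent* variant is flagged as a
mutation candidate under a two-level rule: either all other variants share
one identity and it differs (e.g. one Asp against four Glu), or all others
share one physicochemical class — hydrophobic, polar, positive, negative,
special — and its class falls outside (e.g. one Lys against Leu/Leu/Ile/Leu,
all hydrophobic). Strict identity alone would miss the second pattern, and
class comparison alone would miss the first; the disjunction captures both
single-outlier situations while columns with two or more stray variants are
reported as non-conserved but never auto-flagged, since no single
substitution would reconcile them.

## Coevolution scoring

Alignment rows are filtered hhfilter-style: coverage is the non-gap
fraction over the reference's non-gap columns (rows < 75% dropped), then a
greedy redundancy pass in input order (reference first, always kept) drops
any row whose identity to an already-kept row exceeds 90%, identity being
matches over mutually non-gap positions. These semantics are stated
explicitly because coverage/identity definitions vary between tools; the
filter is idempotent.

The built-in pair scorer is plug-in mutual information with the
average-product correction, raw(i,j) = MI(i,j) − MI_i·MI_j/MI̅, which
removes the shared per-column background that inflates raw MI at variable
columns. Gaps count as a 21st symbol by default (a gap-exclusion mode is
available). Pseudo-likelihood / DCA inference is deliberately not
implemented — the scorer sits behind a pluggable seam, and an externally
computed score matrix can be imported as a square TSV and pushed through
the identical post-processing. The significance step implements
below-average nulling: the mean of the off-diagonal upper triangle of the
raw scores is the threshold, entries strictly below it are masked, entries
equal to it are retained, and surviving scores are z-scored over the same
support for reporting (a zero-variance matrix scales to zero with a
warning). The mean threshold is applied to raw scores; scaling is for
reporting only.

## Orchestration

`run_pipeline` executes simulate → featurize → train → embed → analyze from
one YAML config with a single global seed from which stage seeds are
derived deterministically. Every intermediate is persisted in an open
format (TSV, npz), SHA-256 digests are recorded in a JSON manifest, and a
stage is skipped on re-run when its inputs and outputs are unchanged.
Validation aggregates all config problems into one report before any stage
runs; the CLI distinguishes validation failures (exit 2) from runtime
failures (exit 1).

## Problem sizes

The bundled study scenarios train on 2 × 1000 frames of 21 pseudo-residues
(2000 matrices of 22×22 after padding, 1600 training) with a 100-epoch
training cap, which a single CPU completes in about two minutes per
scenario; the two-regime separation is fully developed well before the cap,
and longer training does not improve it. Unit-test
fixtures use a few hundred frames; the statistical tests of the generators
use 5000–10000 draws, sized so that their tolerances sit at ≥3 standard
errors.

## Known limitations

* The MI+APC scorer is a significance-pipeline stand-in, not a
  pseudo-likelihood model; it underperforms DCA-family methods on real
  alignments with strong phylogenetic structure.
* Silhouette quantifies linear-geometric cluster separation in the latent
  space; a regime judged "overlapping" could still differ in density or
  higher-order structure.
* Training reproducibility is bit-exact only on a fixed machine/BLAS;
  across platforms the convergence epoch may shift by a few epochs.
* The PDB reader supports only blank/'A' altlocs, no insertion codes and
  no mmCIF; trajectories in binary formats (DCD/XTC) must be converted
  upstream.
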