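# Methods

This note records the model as implemented, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical decisions a maintainer would want to know.

## Model

A protein backbone is reduced to per-residue N/Cα/C coordinates and a
one-letter sequence. The contact graph joins residue pairs with Cα–Cα
distance strictly below a threshold (default 7 Å, the common contact
cut-off); edge weights are 1/d². Backbone torsions follow the IUPAC
sign convention (trans = π; the implementation is cross-checked against
Bio.PDB and biotite): φ_i = torsion(C_{i−1}, N_i, Cα_i, C_i) and
ψ_i = torsion(N_i, Cα_i, C_i, N_{i+1}). φ of the first residue and ψ of
the last are undefined, as is any torsion spanning a chain break;
undefined angles are carried as validity flags, never as sentinel
values.

Node features are [sequence embedding ‖ RBF(φ/π) ‖ RBF(ψ/π) ‖ mask
flag], with 16 RBF centers evenly spaced on [−1, 1] and kernel shape
γ = 10 (at γ = 10 adjacent kernels overlap at ≈ e^{−0.044}, a smooth
code of the angle). Undefined angles encode as an all-zero RBF block
with flag 0; masked residues as all-zero blocks with flag 1. The flag
channel exists precisely to keep "masked" distinguishable from
"undefined at a terminus" — without it the two alias.

The GNN uses sum aggregation weighted by the edge feature and a purely
linear per-layer combine applied to h^(k−1) + a^(k) (no nonlinearity
between layers; an explicit design reading of "a linear layer for
feature transformation"). At the first layer the sum is formed in input
space and the layer maps input-dim → hidden-dim. Readout is the mean
over nodes. Defaults: 2 layers, hidden width 1280. The test and
acceptance runs use hidden widths 3–32: all properties checked here
(oracle agreement, closed forms, frozen-θ, gradient exactness, task
recovery) are width-independent, and the small widths keep the suite
fast on one CPU.

### Sequence encoder (θ)

The sequence side is pluggable. The built-in stand-in is a trainable
per-amino-acid embedding table (21 rows: the 20 canonical residues plus
X) followed by a fixed symmetric 5-residue window average, plus a
linear projection to the hidden width. It is not a language model and
makes no claim to be one — it is the minimal differentiable parameter
set θ that lets the coupling scheme be exercised and tested.
Alternatively, precomputed per-residue embeddings (e.g. from any
external protein language model) can be loaded from an `.npz` keyed by
protein id; the projection stays trainable and belongs to θ.

### Self-supervised objectives

Distance: T = 30 uniform bins over [2 Å, 20 Å] with clamping at both
ends (the bin count is fixed; the range is a package choice — 2 Å is
below any physical Cα–Cα contact, and the open top bin absorbs all
distal pairs). The head is FC–ReLU–FC on h_i − h_j with softmax output.
The loss averages over ordered pairs i ≠ j; the diagonal is excluded
because h_i − h_i is identically zero and d_ii = 0 would hand the model
a free constant class. With all-zero head weights the loss is exactly
ln T, which the tests assert to 1e−9.

Angles: the masked set M holds max(1, round(0.15·L)) residues
(half-up rounding), sampled uniformly without replacement from residues
whose φ and ψ are *both* defined; proteins with no such residue skip
the angle task but still contribute the distance term. The loss is a
sum (not mean) over M of squared errors of the normalised angles;
batch aggregation is a mean over proteins. One masked forward pass per
protein feeds both losses — the distance task sees the angle-masked
features with edge weights intact.

Both heads consume the fused representation h_i = h_iˢ + h_i^(K)
rather than the bare GNN output: the fusion is defined before the tasks
and the finetune head consumes the same fused stream, so a single
representation is trained end to end.

An angle-loss caveat: squared error on normalised angles ignores the
2π-periodicity, so a prediction of +0.99 for a truth of −0.99 (nearly
the same physical angle) is scored as maximally wrong. A periodic
(e.g. von Mises) loss would remove this, but is out of scope here.

### MI coupling and the pseudo bi-level scheme

Protein-level vectors are mean-pooled: s_x over the projected sequence
stream, g_x is the graph readout (computed on unmasked features). The
discriminator applies a shared three-layer FC tower with skip
connections and ReLUs to each side and scores the pair by dot product.
Negatives pair each s_x with the structure vector of a different
protein via a seeded within-batch derangement, so a batch of one cannot
form negatives and raises.

The inner step perturbs θ by a single plain gradient-ascent step
θ(ω) = θ + η ∂I/∂θ with η = 5e−5 by default. In `second_order` mode
(the default) the outer gradients of L(θ(ω), ω, α) flow through the
inner step — requiring gradients of gradients, which the autodiff
engine supports because every primitive's backward pass is itself
traced. `first_order` treats θ(ω) as a constant (cheaper, and a hedge
against the instability reported for schemes that actually update the
sequence encoder); `off` reduces the step to plain joint-loss descent,
which the tests verify to 1e−12 per-step gradient agreement. θ itself
is never written to: the contract is checked byte-exactly over full
epochs.

The discriminator β is trained persistently by gradient ascent on I at
every outer step. This is a package decision: some estimate of I must
improve for the inner step to be meaningful, and β — unlike θ — is not
a pretrained asset, so persisting it distorts nothing.

## Optimisation

Adam (β₁ = 0.9, β₂ = 0.999) on ω, α and β with a cosine-decayed
learning rate, lr(t) = lr₀ · ½(1 + cos(π t/T)) indexed by epoch,
lr₀ = 1e−3, 10 epochs by default; the inner θ-step is plain gradient
ascent, not Adam. Batch size defaults to 8 proteins. Non-finite
gradients abort the run and return the last end-of-epoch snapshot.
Training is deterministic given the seed: every random choice (init,
batch order, masks, derangements) derives from it.

## Finetuning

A purely linear head is trained on the mean-pooled fused protein
vectors (Adam, lr 1e−4, 5 epochs, cosine decay); `full` mode also
updates ω, `head_only` freezes it. Two choices make the linear probe
well-posed at these settings: the head starts from zero weights, and
the pooled features are standardised per dimension with statistics
frozen once from the training set at the pretrained parameters. The
composition is still affine, so the head remains strictly linear;
without the standardisation the unnormalised pooled vectors (whose
scale grows with chain length and contact density) saturate the softmax
at a random init and no useful gradient survives five epochs.

## Synthetic data

The generator grows chains from ideal internal coordinates (N–Cα
1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; angles C–N–Cα 121.7°, N–Cα–C
111.2°, Cα–C–N 116.2°; ω fixed trans), which makes recovered torsions
match the requested ones to machine precision and gives the realistic
≈ 3.8 Å consecutive Cα spacing. Three conformation families: ideal
α-helix (φ = −57°, ψ = −47°), ideal β-strand (−120°, +120°), and random
coil with torsions uniform on (−π, π]. Sequences are uniform over the
20 canonical residues, independent of structure (except in tests that
deliberately tie them). Labelled datasets are balanced mixtures with
label = generator type.

What this emulates: known geometry, chain breaks, PDB round-tripping,
class structure separable from backbone geometry. What it does not:
side chains, excluded volume (coils may self-intersect), realistic
sequence–structure dependence, structural noise, or domain/length
distributions of real proteomes. Passing tests therefore demonstrate
the *mechanics* — graph construction, losses, gradients, contracts,
trainability — not biological performance; the benchmark accuracies
reported for GPU-scale pretraining on real structure databases are out
of scope by design.

## Numerical choices and degenerate inputs

- Strict inequality d < threshold for edges; coincident Cα positions of
  distinct residues are an error (1/d² undefined).
- Distances below/above the bin range clamp into the boundary bins.
- Torsions of collinear atom triples are undefined → validity flag
  false (never an exception in table construction).
- PDB input keeps the first model, resolves altLocs to the first, drops
  residues missing any of N/CA/C and records a chain break before the
  next kept residue (a residue-number gap also counts as a break);
  unknown residue names map to X. Chains with fewer than two complete
  residues are dropped; a file yielding none raises.
- The PDB writer emits single-model single-chain ATOM records (N, CA, C
  only, occupancy 1.00, B 0.00), the minimal dialect every reader
  accepts; coordinates round-trip to the format's 1e−3 Å precision.
- softmax/log-sum-exp use constant max-shifts (exact at every
  derivative order); softplus and its sigmoid derivative are evaluated
  in their stable branches.
- The autodiff engine is float64-only and rebuilds the graph every
  step; per-protein constants (adjacency, pair indices, bin labels) are
  cached across epochs.

## Problem sizes used in tests and the acceptance script

Geometry/graph oracles: 100 random structures, L ≤ 50. Closed forms:
exact at any size. Bi-level gradient: a 24-parameter ω on three 4–6
residue proteins, central differences at ε = 1e−5. Task recovery: 200
training / 40 held-out proteins, lengths 20–40, hidden 32, 10 epochs.
Finetune: 40 pretraining proteins (3 epochs), then 60 train / 20 test
helix-vs-strand. These sizes were chosen so the whole suite runs in
well under a minute of training time on one CPU while every claim being
checked is size-independent.

## Known limitations

- The stand-in sequence encoder carries no evolutionary information;
  conclusions about coupling to a *real* protein language model require
  plugging in external embeddings.
- The angle loss is non-periodic (above).
- Second-order mode costs roughly 3× a first-order step in graph size
  and is O(|θ|) in memory; for the widths used here this is negligible,
  but a 1280-wide encoder table would make first-order mode the
  pragmatic default.
- `mi_estimate` is a lower bound estimated on small batches; its value
  is logged per step but no claim is made that it approximates the true
  mutual information.
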