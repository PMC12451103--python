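# Methods

## Problem and model

Small molecules bind RNA at pockets formed by its three-dimensional fold.
`mvsite` classifies every nucleotide of an RNA chain as binding-site or
not, where a binding-site nucleotide is one with at least one atom within
4.0 Å (inclusive) of any atom of a bound ligand, water excluded.

Each RNA is represented as one node set (the nucleotides) carrying an
initial feature matrix `X_init` and three undirected edge sets:

* **primary (P)** — k-nearest neighbors by sequence separation `|i−j|`,
  default `k = 13`;
* **secondary (S)** — backbone adjacency plus all annotated base-pair,
  base-ribose and base-phosphate interactions;
* **tertiary (T)** — k-nearest neighbors by Euclidean distance between
  representative atoms (C4′, centroid fallback), default `k = 8`.

k-NN selection breaks distance ties toward the lower index and the union
of directed selections is symmetrized, so message passing uses the
symmetric renormalized adjacency `Â = D̃^{−1/2}(A + I)D̃^{−1/2}`.

One network layer runs a graph convolution per view,
`H_k = ReLU(Â_k X W_k)`, and fuses the per-view node vectors with
multi-head self-attention in which the three views are the attention
tokens of each nucleotide (attention mixes views, never nucleotides).
With `Attn` the multi-head attention output and `FFN` a two-layer ReLU
network applied to `Attn`, the fused tokens are

    X_fused = LN( LN(H + Attn) + FFN(Attn) ),

re-concatenated to one `n × 3d` matrix. This double-residual wiring, with
the feed-forward branch consuming the raw attention output rather than
the first layer-norm's output, is intentional and preserved as such in
the straight-line oracle used by the tests.

Layers are wired asymmetrically: the fused matrix of layer ℓ feeds only
the tertiary-view convolution of layer ℓ+1, while the primary and
secondary branches propagate their own post-ReLU view outputs. Three
layers give node-aware, local and global fused matrices; an MLP maps each
to a common width `d_scale`, and a linear projection of `X_init` supplies
the smallest scale `Z_Node`. A shared-projection single-head
self-attention over the four scale tokens produces enhanced vectors whose
elementwise mean `Z_f` feeds a two-layer MLP classifier ending in a
sigmoid; probabilities at or above 0.5 are called positive. AUC is always
computed from probabilities, never from calls.

## Features

`X_init` concatenates fixed-order blocks: conservation (1), language-model
embedding (`d_emb`, an input — the package never runs a language model),
one-hot base identity in channel order A/U/G/C (4), secondary block (5:
secondary-graph degree plus base-ribose, base-phosphate, non-canonical
pair and loop flags), topological block (5: degree, neighborhood
connectivity, normalized betweenness, clustering coefficient, per-component
eccentricity, computed on the tertiary graph), and solvent accessibility
(1, an input). Conservation is `1 − H/2` with `H` the column Shannon
entropy over {A,U,G,C}, gaps excluded from the frequencies so 2 bits is
the correct maximum; columns where only the query holds a nucleotide score
0 with a warning. Continuous columns are z-scored with statistics fitted
on the training chains only, to avoid test leakage; flag columns are left
untouched. Missing optional blocks (conservation, embeddings, ASA) are
zero-filled without changing the layout.

## Training

Mean per-nucleotide binary cross-entropy, Adam at learning rate 6e-5,
batch size 30 RNA graphs, 200 epochs. Graphs are processed independently
within a batch (equivalent to block-diagonal batching: no messages cross
RNAs). No class weighting by default despite the ~1:2.2 positive:negative
imbalance; a `pos_weight` switch exists but is off. The returned
checkpoint is the epoch with the best validation AUC; validation is a
deterministic whole-chain split (default one tenth of the chains,
`ceil((1−f)·m)` chains to train). The network is implemented on a small
reverse-mode autodiff engine over numpy (`mvsite.nn`); weights are
Glorot-uniform with zero biases from a config seed, layer-norm eps 1e-5,
dropout (default 0.1) applied to the attention output and FFN hidden layer
during training only, drawn from the training RNG so runs are exactly
reproducible given the seed.

Ablation switches mirror the architecture: `prim_str`/`sec_str`/`ter_str`
remove a view's graph *and* its fusion token (remaining views keep their
wiring; if the tertiary view is removed no branch consumes the fused
matrix); `prim_feat`/`sec_feat`/`ter_feat` zero the view's feature block
and leave all graphs intact; `msf` replaces attentive scale fusion with
plain concatenation of the four scale embeddings (the classifier input
widens accordingly). A sweep harness retrains across tertiary-k values
and layer counts, reporting MCC and AUC per setting.

## Synthetic data

The generator is first-class, tested code, and defines the package's
study conditions. Residues (three atoms each: P, C4′, N1) sit on an
idealized A-form-like helix — rise 2.81 Å, twist 32.7°, backbone radius
9.4 Å — with Gaussian coordinate noise (default SD 0.3 Å). A pocket of
`pocket_size` residues contiguous in 3D is chosen and one ligand atom is
placed 3.2 Å radially outward of each pocket residue's phosphate;
placement is verified against the labeling rule and retried (bounded)
until every pocket residue is within 4.0 Å of the ligand and every
non-pocket residue farther than 4.5 Å. The 0.5 Å exclusion margin keeps
the inclusive 4.0 Å boundary unambiguous, so planted pockets equal the
contact-rule labels exactly. A hairpin-like annotation (canonical stem
closing a flagged loop, plus a few non-canonical/backbone contacts, never
pairing backbone neighbors) and an MSA with planted conserved columns
accompany each chain.

The benchmark dataset is 40 RNAs of 25–45 nucleotides, pocket fraction
~0.31 of the chain (matching the ~950:2104 positive:negative balance of
a realistic training corpus), embedding width 16 and MSA depth 30 at desk
scale. The learnable signal is a shift of `pocket_signal_strength`
(default 2.0) column-SDs added to the conservation and ASA values of
pocket residues. What passing tests show is therefore that the pipeline
propagates and exploits a feature-plus-geometry signal end to end — not
that the model attains any particular accuracy on experimentally solved
RNA: real structures have irregular geometry, correlated features,
modified residues and much weaker, structure-mediated signal.

## Numerical and design choices

* Unstated widths default to `d_hidden = 128`, `d_scale = 128`, 4 heads,
  FFN 4× width, classifier hidden 64, dropout 0.1 — conventional
  transformer/GCN settings, all config-overridable. The desk-scale
  experiments in the tests and the acceptance script use
  `d_hidden = d_scale = 32` with 2 heads, a problem size that trains in
  about a minute per run on one CPU.
* Self-loops exist only inside the normalized adjacency; stored edge sets
  never contain them.
* Representative coordinate: C4′ with centroid fallback,
  config-switchable; a distance-cutoff contact graph
  (`build_contact_graph`, default 8 Å) is available as an alternative to
  the tertiary k-NN graph, and `asa_proxy` offers a clearly non-canonical
  geometric stand-in (negated neighbor count within 8 Å) when no computed
  accessibility table exists.
* The view-fusion tokenization is switchable (`mhvf_tokens`): the default
  treats the per-view vectors of one nucleotide as the attention tokens;
  the alternative reading attends over nucleotides on the concatenated
  width. The default is used everywhere because fusing *views* is what
  motivates the block; the alternative exists for comparison only.
* MCC returns 0 when any factor of its denominator is 0; AUC uses the
  Mann–Whitney rank statistic with average ranks for ties and is reported
  as missing (not 0.5) for one-class data; the decision boundary 0.5 is
  assigned to the positive class.
* Internal indices are 0-based with edge tuples ordered `i < j`; external
  files are 1-based and converted at the I/O boundary. Only the first
  model of multi-model PDB files is read, alternate locations resolve to
  the first conformer, and modified residues stay in the graph as base
  "other" with a zero one-hot row.
* Multi-chain RNAs are out of scope at the reader level: one chain is
  read at a time and any concatenation policy is the caller's.

## Known limitations

The helix generator does not produce realistic tertiary folds, pockets in
deep grooves, or sequence–structure consistency beyond a stem/loop
sketch. Embeddings and ASA are synthetic stand-ins for precomputed inputs.
Training at width 128 on hundreds of long chains is possible but slow on
one CPU; the numpy engine favors transparency and reproducibility over
throughput.
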