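# Methods

This note documents the model implemented in `scsdne`, the choices made
where the design was genuinely open, and what the synthetic fixtures do
and do not demonstrate.

## Pipeline overview

Input is a genes × cells matrix of non-negative expression values with one
cell-type label per cell, plus a directed ligand→receptor database at
gene-symbol level (protein complexes are not modeled). For a chosen
sender type A and receiver type B the pipeline runs:

QC filter → library-size log-normalization → HVG selection → per-type
means → crosstalk matrix S → per-type GRNs → scaling factor μ → joint
matrix X → constrained graph embedding → non-L-R null → percentile
p-values → calls at p < 0.05.

## Preprocessing

* **QC.** A cell is kept iff it detects ≥ `min_genes_per_cell` genes
  (default 200, the droplet-data convention) and its mitochondrial count
  fraction (genes prefixed `MT-`) is ≤ `max_mito_fraction` (default 0.2).
  Filtering is monotone in both thresholds. Synthetic fixtures are
  analysed with permissive QC (`min_genes_per_cell=1`,
  `max_mito_fraction=1`) because the generator produces no low-quality
  cells and no mitochondrial genes; QC thresholds are a property of the
  dataset, not of the method.
* **Normalization.** x → ln(1 + x/total · scale), scale 10⁴ (counts per
  ten thousand). Per cell, Σ(exp(·)−1) equals the scale exactly.
* **HVG.** Top `n_hvg` genes by dispersion = population variance / mean of
  normalized values across all cells of the two selected types (global,
  not per-type), ties broken lexicographically so selection is
  deterministic. A plain dispersion statistic was chosen over any named
  package's variant so the selection has an obvious independent oracle.
  L-R database genes can be force-included (default on in the pipeline):
  a candidate pair that loses its genes before scoring cannot be called.
* **Means.** u_A, u_B are arithmetic means over cells of each type, by
  default on the normalized scale; `means_on_counts=True` switches both
  the means and the constant c to raw counts. The scale used is recorded
  in the run metadata.

## Crosstalk score

score(i,j) = u_iA·u_jB / (c + u_iA·u_jB) with c the mean of the
expression submatrix over cells of both types, on the same scale as the
means. Entries lie in [0, 1), are zero exactly when the product of means
is zero, increase monotonically in each mean, and are invariant under
(u → t·u, c → t²·c). Both cell types are restricted to the common HVG
list, so S is square on a shared gene order.

## Gene regulatory networks

External GRN inference is out of scope; the package accepts a precomputed
adjacency (edge-list or matrix TSV, or MTX with a gene sidecar) and ships
a self-contained co-expression backend: absolute Spearman correlation
over cells of one type, sparsified to the global top-k undirected edges
(ties at the cutoff kept, so the result is permutation-invariant),
constant genes defined to have zero correlation. Either source is passed
through the same sanitizer: entrywise absolute value, then
W_ij = W_ji = max of the mirror pair (absolute value first, so a strong
negative regulatory weight is treated as strong evidence of a
relationship), diagonal forced to zero — self-edges carry no information
for embedding proximity.

Default sparsity is k = 1.5 edges per gene. The budget is deliberately
tight: at the default fixture the genuine co-regulation modules supply
about 1.5·n strong correlations, and widening the budget admits mostly
noise edges (at 5·n fewer than half of the kept edges are real). The
tested design property that ≥ 80 % of kept edges fall within planted
modules holds with a wide margin (measured ≈ 99–100 %).

## Joint matrix and scaling

μ balances regulatory and crosstalk mass: dense mode uses s = ΣS;
sparse-aware mode (default) sums S only over the union support
{(i,j) : W_A[i,j] ≠ 0 or W_B[i,j] ≠ 0}, the reading under which two
sparse GRNs cannot zero out s the way an intersection support typically
would (an intersection option exists behind a flag). X is assembled as
[[W_A/μ, S], [Sᵀ, W_B/μ]]; in dense mode the scaled diagonal mass equals
2ΣS exactly (asserted to 1e-10 relative). Empty GRNs give μ = 0; scaling
is then skipped with a warning and the crosstalk block alone drives the
embedding.

## Embedding

Objective: L = ‖X̂−X‖²_F + 2tr(YᵀLY) + (ν/2)Σ‖W⁽ᵏ⁾‖²_F with L = D−X,
D_ii = ΣX_ij (a 1e-8 floor keeps D invertible for isolated nodes),
subject to YᵀDY = I_d. The printed objective carries no term weights;
`alpha_first` and `nu_reg` default to 1 and are exposed. The classic
β-reweighting of non-zero entries in the reconstruction term is not part
of the printed objective and is omitted.

**Parametrization.** The code matrix Y is optimized directly; a stacked
sigmoid decoder maps y_i back to the node's adjacency row, carrying the
second-order (neighbourhood) term. The encoder half of the classic
autoencoder is deliberately absent: a row-wise encoder applied to X caps
the numerical rank of Y near rank(X)+1 (smooth nonlinearities of a
low-rank input have exponentially decaying singular spectra), and the
crosstalk block — a saturating transform of an outer product — is close
to low rank, so YᵀDY = I is unattainable through an encoder whenever d
exceeds that rank. Direct optimization of Y makes the constraint exactly
satisfiable at any d.

**Constraint handling.** `stiefel` mode (default): project the gradient
onto the tangent space {ξ : ξᵀDY + YᵀDξ = 0} of the generalized Stiefel
manifold (in the D-metric), take a full-batch Adam step, retract with
the polar map Y ← Y(YᵀDY)^{−1/2}; the residual stays at machine
precision and the polar factor is well conditioned because each iterate
is one small step from the manifold. `penalty` mode adds
w·‖YᵀDY − I‖²_F (w = 1000) and takes unconstrained steps; on the 60-node
reference graph it reaches residual ≈ 2.5e-3 in 200 epochs. Training is
double precision, full batch, deterministically seeded (Glorot-uniform
decoder init, Gaussian code init retracted onto the manifold).

**Latent dimension.** Default d = 2n (full). With the exact constraint
and square Y, Y = D^{−1/2}Q for orthogonal Q, so cross distances obey the
closed form ‖y_i − y_j‖² = 1/D_ii + 1/D_jj: the model ranks pairs by
joint connectivity (expression through S, regulation through W/μ), and
the ranking is invariant to where the optimizer stops. Low-dimensional
embeddings (d = 8–64) remain available, but on planted-signal fixtures
the bottom-of-spectrum geometry places co-high-expression partners on
opposite sides of the latent space (their within-block neighbourhood
profiles are similar, their cross-block profiles are not), inverting the
intended ranking; they should be used for visualization, not calling.
Training hyperparameters (Adam, lr 0.01, 200 epochs, decoder hidden
width 128 for low-d and none for full-d) were fixed by watching loss
convergence on development fixtures.

## Significance

Null = latent distances of **all** cross-type gene pairs not present in
the L-R database (per sender/receiver pair; a seeded uniform subsample
caps it at 200,000). p = (weak percentile)/100, i.e. the fraction of null
distances ≤ the pair's distance; the weak (≤) tie convention is fixed so
p ∈ [0,1] with p = 0 only strictly below the null minimum. Calls use raw
p < 0.05 with no multiple-testing correction by default, matching the
thresholding convention of the method; a Benjamini–Hochberg option
exists. The crosstalk score is exported as the interaction-strength
column; it is not a probability.

## Synthetic fixtures

The generator draws negative-binomial counts (dispersion/size 1.0 — the
strong overdispersion typical of droplet data) for two types of 300 cells
over 300 genes by default. Ligand and receptor gene pools are disjoint;
pairs use distinct genes while the gene budget allows (as in real L-R
databases, where sharing is the exception), then reuse genes through a
Latin-square slot map. Planted pairs put the ligand at 5× baseline mean
in the sender and the receptor at 5× baseline in the receiver; decoys
stay at baseline on both sides. Genes outside the L-R pools are split
into 10 co-regulation modules whose members share a per-cell latent
factor (Gaussian copula over NB marginals, latent correlation 0.5),
exercising the GRN channel independently of the crosstalk channel.

What passing tests show: the pipeline ranks product-of-means signal
correctly, its null calibration is honest when candidate pairs are
exchangeable with the null population, the constraint machinery and the
scoring/scaling primitives are exact, and runs are reproducible. What
they do not show: performance on real tissues — no batch effects,
doublets, ambient RNA, dropout structure beyond NB sampling, or
biologically realistic GRNs are simulated, and the planted effect acts
through exactly the lever the score measures. A calibration caveat worth
stating: if candidate L-R genes differ systematically from the null
population in graph degree (for example, genes embedded in strong
regulatory modules versus isolated ones), percentile p-values inherit
that difference; the signal-free calibration fixture therefore uses a
database large enough that its genes tile the whole gene pool and are
exchangeable with the null by construction.

## Degenerate inputs and numerical conventions

Zero-total cells are a normalization error (filter first). All-zero
expression submatrices make c undefined → error. μ = 0 (empty GRNs) skips
scaling with a warning; s = 0 in sparse-aware mode errors with a pointer
to dense mode. Isolated joint-graph nodes receive the 1e-8 degree floor.
Dispersion uses population variance (ddof 0). Result tables print six
significant digits and round-trip at that precision; ties in the output
ordering break by latent distance.

## Known limitations

Sender and receiver types are chosen by the user; the package loops over
type pairs only mechanically (`--all-pairs` style iteration in user
code). Gene-symbol matching is case-sensitive unless `ignore_case` is
set. Subunit complexes, spatial context, pathway enrichment and
comparisons against other callers are out of scope. The full-dimensional
embedding costs O((2n)³) linear algebra per epoch (dense decoder matmuls
plus, in stiefel mode, the eigendecomposition of the 2n×2n Gram matrix
behind each retraction), which is comfortable up to a few thousand HVGs
and not intended for whole-transcriptome node sets.
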