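# Methods

`tcquant` quantifies *transition cells* (TC) — cells caught between discrete
expression states — in single-cell expression matrices, and ships two
generative models of the epithelial–mesenchymal transition (EMT) that serve
both as ground-truth data generators and as analysis tools. This note
records the models, the defaults, and the numerical and design choices.

## The transition-cell pipeline

**Input and filtering.** The input is a genes × cells non-negative matrix.
Cells expressing fewer than 5% of genes are removed; genes expressed in
fewer than 10% of cells or with population variance below 0.005 are removed
("expressed" = strictly positive, which covers both qPCR-style continuous
values and UMI counts). Each surviving gene is then fitted with a
three-component univariate Gaussian mixture (EM, k-means++ initialization,
5 restarts, variance floor 1e-6, seeded). Genes whose near-zero component
(fitted mean within 10% of the value range of zero — fitted means are never
exactly zero) carries more than 90% of the weight are dropped as
dropout-dominated. The rest are ranked twice — by descending separation of
the two heaviest components' means and by ascending difference of their
weights — and the rank sum selects the top 3000 genes. "Top two components"
means the two heaviest by weight; rank ties break on gene name so the
selection is deterministic. Expression is used as loaded; a `log_transform`
flag applies `log1p` before the mixture fit for count-distributed data.

**Consensus matrix.** Cell–cell similarity is the co-clustering frequency
over an ensemble of k-means runs on the top-d principal components
(log1p + per-gene standardization first), for d ∈ {5, 10, 15, 20, 30}
(clipped to the data), base cluster counts k ∈ {2..12} and 3 seeded
restarts, each run on a random 80% cell subsample. Pair frequencies are
normalized by the number of runs in which both cells were drawn. The
subsampling matters: k-means on well-separated data is deterministic, so
without resampling a borderline cell never changes side and every
membership row collapses to a point mass. Resampling perturbs the centroids
and the partition boundaries, so genuinely ambiguous cells accumulate
fractional co-membership with both of their flanking states. Mixing coarse
(k = 2, 3) and fine partitions gives the consensus both global structure
and within-axis resolution.

**Cluster count.** k is the position of the largest gap in the ascending
eigenvalues of the symmetric normalized graph Laplacian
L = I − D^(−1/2) M D^(−1/2), searched over j ∈ [2, k_max] (k_max = 10 by
default; ties toward smaller j; k = 1 is never reported since a transition
analysis needs at least two states). The user can override k — real
analyses often fix it from prior knowledge.

**Soft clustering and CPI.** M is factorized by symmetric NMF,
min_{H≥0} ‖M − HHᵀ‖²_F, via projected gradient descent with Armijo
backtracking (monotone by construction), initialized from the absolute
top-k eigenvectors of M scaled by √eigenvalue, with 10 multiplicatively
perturbed restarts, relative-objective tolerance 1e-6, 500 iterations.
Columns of H are ordered by the row index of each cluster's
highest-membership cell so output is deterministic up to the data. Row
normalization gives the membership matrix P, and the Cell Plasticity Index
is the normalized entropy CPI_i = −(1/log k) Σ_j P_ij log P_ij ∈ [0, 1].
TC are cells with CPI above a threshold; the default is automatic (Otsu's
method on the CPI distribution) because published analyses use
dataset-specific cutoffs (e.g. 0.34) without a stated rule.

**Embedding (PRE).** Cluster centers come from HᵀH normalized to a
cosine-style similarity S (unit diagonal), converted to distances
d_ij = √(s_ii + s_jj − 2 s_ij) and embedded by classical MDS, then rigidly
oriented (center 1 at origin, center 2 on +x, center 3 with +y). Cells
minimize Σ_ij p_ij‖x_i − a_j‖² − (λ₁/n) Σ_il ‖x_i − x_l‖². The objective is
quadratic, so the solver uses the exact stationarity system
(1 − 2λ₁)x_i + (2λ₁/n)Σ_l x_l = (Pa)_i. On the zero-sum subspace the
quadratic form has coefficient 1 − 2λ₁, so boundedness requires λ₁ < 1/2
strictly; the default is λ₁ = 0.3. At λ₁ = 0 every cell sits at its
membership-weighted centroid of the centers.

**Trajectories and pseudotime.** Each TC is attributed to the unordered
pair of its two largest memberships (ties toward the smaller cluster
index). Clusters joined by at least one TC are neighbors; a cluster with TC
toward every other cluster is an intermediate-cell-state (ICS) candidate.
Trajectories are simple paths from a user-chosen (or automatic: the non-ICS
cluster with the fewest surrounding TC) initial cluster, explored with
branches in descending TC count; each path collects the cells whose argmax
cluster lies on it and is scored by the collected fraction of all cells.
Cells are ordered per consecutive pair (a → b): residents of a by ascending
CPI (the start cell — highest membership in the initial cluster — forced
first), then cells aligned between a and b with argmax b by descending CPI;
cells already placed are skipped and final-cluster stragglers close the
ordering. Raw pseudotime is the cumulative embedding distance along this
ordering (a straight-line "direct" mode exists; cumulative preserves
monotonicity on curved paths). Each between-cluster segment is min–max
rescaled to [s, s+1] so segments are comparable across trajectories, and a
cell's global pseudotime is its minimum over the trajectories containing
it; cells on no trajectory are reported missing.

**Marker and transition genes.** On the cells of one trajectory,
min_{H̄,W≥0} ‖D_s − H̄W‖²_F − λ₂ Tr(H̄ᵀH_s) ties a fresh factor H̄ to the
consensus-derived memberships and yields the gene–cluster matrix W
(λ₂ = 10). The raw objective is unbounded below along H̄ → cH̄, W → W/c, so
a small ridge (10⁻³‖H̄‖²) anchors the scale; both multiplicative half-steps
are monotone. After per-gene column normalization of W, a gene marks the
cluster with its largest entry when the top-two gap exceeds 0.03; ICS often
have empty marker lists, which is expected behavior, not failure.
Transition genes between neighboring clusters are the two clusters' markers
whose expression correlates monotonically with the aligned ordering,
|Spearman ρ| ≥ 0.64 (average ranks on ties; constant genes skipped), the
sign giving the direction. A flag widens the candidate set to all genes.

## The agent-based EMT simulator

The module treats the regulatory network as data (species names and named
parameters, YAML-loadable), so any published EMT circuit parameterization
can be dropped in verbatim. The shipped default is an effective 18-species
circuit authored for this package with the required qualitative structure:
three cascaded bistable switch modules — SNAIL (gated by TGF-β), ZEB (gated
by SNAIL) and TWIST (gated by ZEB), each a self-activating factor standing
in for a double-negative loop with its microRNA antagonist — plus
epithelial (Ecad, Grhl2, Ovol2, Klf4, Esrp1, Crb3, miR-34, miR-200,
miR-1199) and mesenchymal (Vim, Ncad, Fn1, Mmp9, Slug) readouts. A switch
that is "off" while its gate is active rests at a basal level (0.32) close
enough to the bistable threshold (~0.7) that division noise can ignite it,
so state transitions flow in both directions along E ⇄ I1 ⇄ I2 ⇄ M; a
switch whose gate is inactive rests near zero and cannot ignite, which
enforces the cascade order. At the defaults the circuit has exactly four
stable steady states, labeled by Ecad/Vim dominance (E highest Ecad, M
highest Vim, I1 the Ecad-dominant and I2 the Vim-dominant hybrid), verified
by relaxation from ~1000 random initial conditions plus a Jacobian
eigenvalue check.

All rates share a first-order decay constant λ = 0.03 h⁻¹ (protein
half-life ≈ 23 h, within the measured mammalian range). This sets the
relaxation time after a division perturbation to ~100–150 h against a
700 h division cycle, so a first-cycle snapshot holds roughly 20% mid-transit
cells — the regime the pipeline is meant to resolve. Gene dynamics follow
dI = f(I)dt + σ I dW (Euler–Maruyama, dt = 0.1 h, σ = 0.01, states clamped
at 0). Cells divide after truncated-normal N(700, 200) h intervals with a
per-lineage budget (daughters inherit budget − 1; initial budgets uniform
on {2..7}); daughters receive state ± state·N(0, 0.7) per species; once the
budget is spent a cell dies after a further truncated-normal N(1000, 100) h.
"Five cycles" is interpreted as five mean division times of global
simulated time with a snapshot every 700 h. The default initial population
is 50 cells at each attractor. Phenotype labels compare a cell's state to
the attractors: nearest attractor within a radius of 20% of the minimum
inter-attractor distance, otherwise TC. The radius sits above the
stationary SDE spread of a settled cell (sd ≈ σI/√(2λ) per species), so
cells fluctuating around a steady state are not mislabeled as transiting;
it remains well inside the basin boundaries. A variant flag restricts
proliferation to chosen phenotypes (e.g. non-proliferative I1), and the
lineage table records each mother's phenotype at division for auditing.

What the generator does *not* emulate: technical dropout, library-size
variation, sequencing depth noise, doublets, batch effects, or thousands of
genes — its 18 dimensions are the regulatory species themselves. Passing
the recovery tests therefore shows the pipeline resolves genuine dynamical
intermediacy; it does not certify performance under scRNA-seq technical
noise.

## The ICS population model

Population fractions follow a linear compartment chain: direct E → M at
unit rate with reverse rate α, and an indirect route through N intermediate
states at rate γ with reverse rates βγ. For N = 0 the system reduces to
dE = αM − E, dM = E − αM with the closed form
M(t) = (1/(1+α))(1 − e^{−(1+α)t}); the N = 1 intermediate receives
γE + βγM and loses γ(1+β)I₁, the limit consistent with both chain ends.
The deterministic solve is the exact eigendecomposition of the rate matrix
(stiffness-proof for large γ or N) on a horizon of ~18 slowest relaxation
times, with M(∞) from the null space; metrics refuse trajectories whose
tail still moves by more than 10⁻⁶ relative. The stochastic variant adds
σ dW (σ = 1) to the epithelial equation and integrates by Euler–Maruyama
with a stability-safe step (min(0.01, 0.5/|λ|max); sweeps use dt = 0.002,
T = 100); E is reflected at zero by default, with an exact-linear unclamped
mode for ensemble-mean checks.

Metrics: AS = (max_t M − M(∞))/max_t M (zero for the two-state system,
whose response is monotone); TE = M(∞); NA = the coefficient of variation
of the stochastic M over the final half of the horizon, computed per path
and averaged over a 100-path ensemble (single-path CV is also available but
far noisier). Because noise enters only the epithelial equation while the
rate-matrix columns sum to zero, total mass performs a random walk shared
by every parameter setting; sweeps therefore reuse the same seed and step
size at every grid point (common random numbers), which makes orderings
across the grid reflect the systematic parameter effect rather than
sampling noise.

α and β are exposed as required configuration; the defaults α = 7,
β = 0.01 were chosen by numerical exploration as a single regime in which
all of the model's qualitative behaviors are visible simultaneously on
small grids: at N = 2, NA decreases and TE increases monotonically in
γ ∈ {5, 20, 80} while AS peaks at the middle value; at γ = 80, AS rises and
NA and TE fall as N goes 1 → 4 → 8; and long chains (N = 12, γ = 40)
produce oscillatory adaptation with multiple local maxima of M(t).

## Numerical conventions and limitations

* All stochastic components take explicit seeds; the pipeline derives
  per-stage seeds from one master seed via `SeedSequence` so stages can be
  re-run in isolation. Repeated runs are byte-identical.
* 0·log 0 = 0 in the CPI; CPI is clipped to [0, 1] against rounding.
* Degenerate pseudotime segments (single cell, zero spread) map to the
  segment's left endpoint.
* Ties: top-two memberships toward the smaller cluster index; gene-rank
  ties lexicographic; eigengap ties toward smaller k.
* The symNMF objective is non-convex; restarts reduce but cannot eliminate
  the chance of a poor local minimum on adversarial inputs.
* The consensus ensemble is O(runs · n · d · k) and the factorization
  O(n²k) per iteration; the pipeline is comfortable at 10³–10⁴ cells but
  has no sparse/ANN path for much larger atlases.
* Problem sizes used by the test suite and the reproduction script (a
  ~300-cell first-cycle snapshot for recovery, 1000 relaxations for the
  attractor census, 100-path ensembles for NA, 20×20 planted matrices for
  operator oracles) were chosen as the smallest sizes at which each
  property is stably expressed.
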