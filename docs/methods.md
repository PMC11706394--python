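# Methods

## Model and assumptions

The package models a weighted undirected network `G` (symmetric, nonnegative,
zero diagonal) as a linear time-invariant system `x' = Ax + Bu`, `y = Cx`.
Linearity and determinism are assumptions, not claims about the underlying
system: for brain networks they are the usual local approximation of
macroscale dynamics, and all conclusions are conditional on them.

**Stabilization.** `A = G − cI` with `c = λ_max(G) + ε`. The default
`ε = 2e-16` (order machine epsilon) makes the spectrum strictly negative —
so the infinite-horizon Gramian exists — while perturbing the dynamics as
little as possible. Because the shift is diagonal it leaves the graph
Laplacian, and hence every eigenmap, untouched. `ε` is exposed everywhere it
matters; larger values (e.g. 0.1–0.5) give well-damped systems that are
convenient for high-precision cross-checks.

**Spectral projection.** `L = D − G` is decomposed as `V Λ Vᵀ` with
ascending eigenvalues. Eigenvector signs follow a fixed convention (the
largest-magnitude entry of each column is made positive, ties to the first
index) so selections are reproducible across linear-algebra backends. The
output matrix is `C = H_r Vᵀ`; two selection modes exist:

- `magnitude` (default for control tasks): the `r` eigenmaps with largest
  `|(Vᵀ x_f)_i|` — most informative about the desired final state;
- `lambda` (default for centrality): the first `r` eigenmaps — the coarsest
  topological scales, defined without reference to any state.

Degenerate Laplacian eigenvalues are ordered as the backend returns them
(then by index); projected-Gramian spectra are invariant to the ordering of
selected maps, so centralities do not depend on this choice.

## Optimal control

The soft-constrained cost `J_ρ = ‖y_f − y(t_f)‖² + ρ∫‖u‖²dτ` has the unique
minimiser

    u*(τ) = Bᵀ e^{Aᵀ(t_f−τ)} Cᵀ (ρI_r + C W(t_f) Cᵀ)^{-1} (y_f − C e^{A t_f} x₀),

with `W(t_f)` the finite-horizon Gramian. For symmetric `A` (every network
here) `W(t_f)` is evaluated exactly in the eigenbasis via
`F_ij = (e^{(μ_i+μ_j)t_f} − 1)/(μ_i + μ_j)` (`expm1` keeps near-zero sums
accurate); non-symmetric inputs fall back to the Van Loan augmented-matrix
exponential. Hard terminal constraints and trajectory-tracking costs are
deliberately out of scope.

**Metrics use the simulated trajectory.** `u*` is sampled on the `dτ` grid
(`t_f/dτ + 1` points, input defined on `[0, t_f)`) and injected into the
forward-Euler recursion `x_{k+1} = x_k + dτ(Ax_k + Bu_k)`; `δ`, `η` and `E`
(left Riemann sum) are computed from that trajectory. This mirrors how a
practical controller would be deployed and deliberately inherits the
dτ-sensitivity of the integration; the closed-form terminal output differs
by O(dτ). The Euler stability condition `dτ < 2/max|Re λ(A)|` is checked and
violations are flagged, not fatal. Cosines against zero-norm targets are
reported missing (`None`), never zero. For target (subnetwork) control, `η`
is computed on the target substate, matching the restricted output.

Defaults: `ρ = 1e-4`, `t_f = 1`, `dτ = 0.01`. Named presets ship for
per-driver-count regularization on weighted brain-like networks
(`RHO_PRESET_BRAIN`: 0.0043/0.0121/0.0234 for 1/8/64 drivers) and for the
uniform-modular state configuration (`RHO_PRESET_MODULAR`). The physical
time rescaling `Ã = −A/(τ̃ λ_fast)` maps the fastest communication mode onto
an interareal conduction delay (default τ̃ = 0.0102 s).

## Projected-Gramian centrality and its numerics

`W = ∫₀^∞ e^{Aτ}BBᵀe^{Aᵀτ}dτ` solves `AW + WAᵀ + BBᵀ = 0`; the worst-case
centrality is `λ_min(W)` and its low-dimensional counterpart is
`λ_min^EIG = λ_min(C W Cᵀ)`. Targets restrict `W` to the target rows/columns
*after* solving on the full system — drivers act through the whole network,
so indirect paths count — and project with the subnetwork's own eigenmaps.

Machine-epsilon stabilization makes these numerics genuinely delicate, and
the package's scheme is built around two observations:

1. `eigh(A)` cannot resolve an eigenvalue of `−2e-16` (absolute accuracy is
   ~1e-15·‖A‖). The spectrum of `A` is therefore derived from `eigh(G)` with
   the shift applied analytically, making the slowest (Perron) mode exactly
   `−ε`.
2. That mode contributes a PSD component of magnitude up to `1/(2ε) ≈ 2.5e15`
   to every Gramian. Any explicit matrix containing it loses ~15 orders of
   magnitude of spectral resolution. The engine therefore keeps the
   slow-mode component (the Perron mode plus any mode degenerate with it,
   as in disconnected or mirror-symmetric graphs) in factored form and,
   when extracting minimum eigenvalues, either absorbs boosted directions
   exactly (when their strength is comparable to the regular part) or
   deflates them analytically (error O(‖W_reg‖²/strength) ≤ 1e-8 relative).

Without this scheme the projected minimum eigenvalues come out as large
negative rounding artefacts — the same unreliability that makes the
unprojected `λ_min` uninterpretable for single drivers on networks beyond a
few dozen nodes. With it, `λ_min^EIG` is positive and stable for `r` up to a
network-dependent critical dimension `r*`, scanned upward from 1 with a
positivity tolerance of 1e-12 (exposed in the API). On 128-node hierarchical
modular networks `r*` is typically 5–8.

## Synthetic generators

**HMSW.** `2^(levels−1)` fully connected base clusters of
`initial_cluster_size` nodes are merged pairwise over `levels − 1` levels;
at merge level `l` the node pairs spanning the two merged blocks are wired
independently with probability `p_l = p₂ / falloff^{l−2}`. `p₂` is
calibrated linearly so the expected overall density hits `target_density`
and clipped at 1; at the reference parameters (n=256, 8 levels, density
0.035, cluster size 2, fall-off 2.5) the calibration sits marginally past
the clip, giving expected density ≈ 0.0349 (0.3% low). Disconnected
realisations (possible at low density) are repaired with single random
bridging edges, counted in the density and flagged in the output. The exact
wiring rule of published hierarchical-modular generators varies; this
scheme is the simplest that reproduces the stated summary parameters
(cluster size, per-level fall-off, mean density) and is declared as the
package's construction.

**ER / BA.** Erdős–Rényi `G(n, p)` and a nonlinear preferential-attachment
model (`P(attach) ∝ degree^γ`, default γ = 2) whose per-node edge budget is
scheduled to match a requested density — an interpretation, since "bias 2"
generators are not standardised.

**States.** Three configurations: `gaussian` (`x₀ = 0`,
`x_f ~ N(μ_f=1, σ_f=10)` — a strongly dispersed departure from rest),
`uniform_modular` (`x₀ ~ U(−1,1)`, `x_f = module_index + U(−1,1)` over the
8-module HMSW level — modular organisation emerging from noise) and
`constant` (user-fixed vectors). All generators are pure functions of
(params, seed).

**What the generators do not emulate:** weighted fiber-count distributions,
spatial embedding / distance-dependent wiring, hemispheric symmetry, and
subject-level variability of real connectomes. Passing tests on HMSW
ensembles therefore validates the *method* (its exact identities, its
direction-of-effect claims, its numerical reliability), not any specific
empirical claim about human brains.

## Experiment protocols and statistics

`run_experiment` executes one factor sweep per call (projection dimension,
target size along the module hierarchy, final-state dispersion, selection
scheme, topology, Euler resolution, state configuration, network size) over
an ensemble of networks, with per-network seeds derived deterministically
from the master seed (`SeedSequence([master, index])`) so runs are exactly
reproducible and parallelisable. Results are tidy long-format tables with a
JSON provenance sidecar.

The headline analysis is a per-driver-count one-way ANOVA of per-network
precision across r ∈ {4, 16, 64, 256} on 100 networks (driver counts
{1, 8, 64}), reporting the minimum F over driver counts; the factorisation
(which observations enter each ANOVA) is the package's own declared choice,
since alternatives (e.g. node-averaged precisions) are equally defensible.
Zero within-group variance with non-zero between-group variance reports
F = ∞ with a flag. Problem sizes used by the shipped acceptance analysis:
100 networks of 256 nodes, ~1200 control solves, a few minutes on one CPU.

## Aggregation choices

- Self/external regulation ratios are reported log10-transformed.
- Meta-graph weights are geometric means over drivers in the source system;
  scores at or below the positivity tolerance (1e-12) are excluded and
  counted, since a geometric mean is undefined at zero and such scores
  signal `r` above the target's `r*`.
- Self-loops are computed and stored in the meta-graph; the control
  unbalance (out-strength minus in-strength) excludes them symmetrically,
  so unbalances sum to zero over systems.
- Hemisphere control targets the full node set of each hemisphere; the
  per-system variant restricts drivers, not targets.
- Weighted betweenness (driver ranking) uses edge length = 1/weight —
  stronger links are shorter paths; binary graphs reduce to the unweighted
  definition. Ties break by node index.

## Known limitations

- The infinite-horizon Gramian at `ε = 2e-16` is meaningful only through the
  factored slow-mode representation; the explicit matrix returned by
  `GramianEngine.gramian` should not be fed to naive eigensolvers when small
  eigenvalues matter.
- At machine-epsilon stabilization, projected minimum eigenvalues below
  ~1e-12 are indistinguishable from rounding; the critical-dimension scan
  treats them as unreliable by construction.
- Directed or signed graphs and normalized Laplacian variants are out of
  scope; inputs are validated as symmetric and nonnegative.
- Single-driver control precision at small r varies substantially across
  network realisations (the reachability of magnitude-selected eigenmaps
  from one driver is topology-dependent); ensemble means are stable but
  per-network values carry sd ≈ 0.2 at the reference conditions.
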