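# Methods notes

## Ancestral reconstruction

**Model.** Sequences evolve under the 20-state equal-exchangeability
(Poisson) model with uniform equilibrium frequencies. Along a branch of
length *b* (expected substitutions/site) at relative rate *r* the transition
probabilities are P(same) = 1/20 + (19/20)·e^(−20rb/19) and
P(different) = (1 − e^(−20rb/19))/20. Discrete-gamma rate heterogeneity is
available (median discretization of a mean-one gamma, equal category
weights). Production studies of this protein family use richer empirical
matrices (LG with gamma rates) inside dedicated phylogenetics software; this
package deliberately uses the analytically tractable model because the
downstream logic being tested — posteriors → altAll → robustness
comparisons — is model-agnostic, and the simple model admits an exact
independent oracle (explicit summation over every internal-state
assignment), so the pruning implementation is verifiable to machine
precision rather than plausible by eyeball.

**Marginal posteriors.** A postorder pass computes conditional likelihoods
of the subtree below each node; a preorder "outside" pass computes the
likelihood of everything else given each state at the node; their
normalized product is the marginal posterior, integrating over all other
nodes. With gamma categories, numerator and site likelihood are averaged
over categories before normalizing. The ML sequence takes the argmax state
per site (alphabetically first one-letter code on exact ties).

**Gaps.** Sites where any tip carries a gap are excluded from the posterior
computation, reported with a warning, and carry the gap symbol in the
reconstructed sequences. Indel history (e.g. lineage-specific terminal
extensions) is outside this package's scope, and excluding such columns
keeps every reported posterior a proper 20-state distribution.

**altAll.** The alternate ancestor swaps in the runner-up state wherever its
posterior is strictly greater than the threshold (default 0.20). Only the
single best alternate is considered: a second alternate above 0.20 would
require the top three states to sum past 1 with the ML state still ranked
first, which can only occur marginally, and in that regime the runner-up is
the defensible worst case. Exact PP ties between ML and runner-up keep the
ML state; ties among alternates resolve alphabetically. The average
posterior probability of a reconstruction is the mean of the ML state's PP
over all non-gap sites — ambiguous sites are not excluded, since dropping
them would inflate the statistic that is meant to flag ambiguity.

**Topology enumeration.** Rooted binary leaf-labeled topologies are
generated by leaf insertion into every edge (plus a new root), giving
(2n−3)!! trees, deduplicated by a canonical sorted-Newick form (children
ordered by their smallest descendant label). Site indices in all reports
are 1-based.

**Fitch parsimony.** Classic bottom-up pass (intersection if nonempty, else
union, counting one change per union). A brute-force minimum over all
internal labelings is kept alongside as the test oracle; the suite checks
agreement across every topology with up to six leaves.

## Densitometry

Lanes are equal-width vertical strips (explicit boundaries may override),
collapsed by summing across the strip. The band window is shared by all
lanes of a gel. Background under the band is the straight line joining the
median intensities of flanking regions (5 positions each side by default),
so a constant offset over the image cancels exactly and a linear gradient
along the migration axis cancels to first order. Band intensity is the
windowed sum above background, floored at zero; each time course is
normalized to its own t = 0 lane (a separate undigested-control gel is not
assumed, since quantities enter the decay fit only as ratios). Pixels at
the 16-bit saturation ceiling trigger a warning but do not halt
quantification.

## Decay and unfolding fits

**Exponential decay.** f(t) = A₀e^(−kt) is fit by unweighted nonlinear
least squares with one (A₀, k) shared across replicates — the global fit.
Fractions are pre-normalized so A₀ ≈ 1; a per-replicate-amplitude variant
(k still global) is available behind a flag. No error model is imposed on
densitometry points, hence unweighted loss. Initializations come from the
log-linear slope of positive points; convergence tolerances are 1e-10 with
a 10,000-evaluation cap. Parameter uncertainties are square roots of the
covariance diagonal at the optimum. Rate contrasts are reported as log₁₀
ratios with first-order propagated errors, since the biologically meaningful
differences here span orders of magnitude.

**Two-state unfolding.** The six-parameter linear-extrapolation model is
fit with analytic starting values: baselines from the three lowest-/
highest-denaturant points, the midpoint from the crossing of the data with
the baseline midline, the m-value from the central slope via
dy/dx|_Cm = (m/4RT)·(baseline separation) + mean baseline slope. Up to five
jittered restarts run if the first start fails or lands at m ≤ 0. R is
0.001987 kcal·K⁻¹·mol⁻¹ with ΔG in kcal/mol and T = 298.15 K. C_m = ΔG/m is
exact by construction; sd(C_m) propagates sd(ΔG), sd(m) and their
covariance (the pair is strongly correlated, so omitting the covariance
would overstate the error severalfold). A midpoint outside the sampled
denaturant range triggers a warning rather than an error. The model is
invariant under affine rescaling of the signal: ΔG, m and C_m are unchanged
while baselines transform accordingly, which the suite checks. Proteins
with coupled ligand binding, folding and oligomerization are not genuinely
two-state; the fit here reports *apparent* stabilities, which is all the
downstream comparisons require.

**Unfolding kinetics.** A single exponential with floating endpoint; when
the fitted relaxation time 1/k is shorter than the instrument dead time, or
the trace has no resolvable amplitude above noise, the result is flagged as
within-dead-time rather than reported as a rate. Reversibility checks are
supported only as unfolding/refolding overlay differences — no statistic is
attached, as none is standard.

## Assay summaries

**Growth inhibition.** Technical replicates are averaged first; percent of
untreated growth is 100·(OD_treated − OD_blank)/(OD_untreated − OD_blank)
at the evaluation time; SEM is taken across biological replicates. Both a
7 h and a 12 h evaluation time are supported (default 7 h) because both are
legitimate readouts — early time separates growth delay, late time
separates carrying-capacity loss — and neither is privileged. The nearest
grid point within half the 15-min sampling interval is used, without
interpolation. An untreated-minus-blank signal ≤ 0 is an error (no growth
to normalize against).

**NF-κB induction.** Per well, firefly/renilla; per treatment, technical
mean; induction = (r̄ − r̄_LPS+PB)/(r̄_LPS − r̄_LPS+PB), so the LPS positive
control maps to 1 and the polymyxin-B-suppressed background to 0 on every
plate, making plates comparable. Mock wells are reported but excluded from
the normalization (only the two anchors define the scale). Negative
inductions are reported as-is. The normalization is exactly invariant to
separate rescalings of all firefly and all renilla counts, which the suite
checks.

## Synthetic data

Generators emulate the *structure* of each data class, not instrument
physics: multiplicative Gaussian noise for gel band areas and luciferase
counts (both are scale-type measurements), additive Gaussian for CD and
OD600. All draws come from per-generator streams derived from the single
`SimSpec` seed, so identical specs reproduce identical data bit-for-bit.
Ground truth is returned with every dataset (and written as JSON sidecars
by the CLI). Realistic gel artifacts (lane smiling, bleed), mechanistic
receptor signaling, and indel evolution are intentionally not modeled —
passing tests demonstrate correctness of the analysis logic under the
stated noise models, not robustness to every instrument pathology.

Preset scales keep the synthetic contrasts study-like: "hA9-like" decay at
0.3 min⁻¹ vs "complex-like" at 3×10⁻⁴ min⁻¹ (three orders of magnitude,
the scale separating protease-susceptible monomeric states from resistant
heterocomplexes) and a stabilizing-substitution preset of ΔΔG = 4 kcal/mol
(ΔC_m = ΔΔG/m). These are illustrative, not measured values.

Default replicate structure mirrors common plate practice (technical
triplicates, three biological replicates). One caveat: with only three
biological replicates, a ±2·SEM interval has ~82% coverage (Student-t with
2 degrees of freedom), so the suite evaluates the 2·SEM-coverage property
of the reporter normalization at ten plates per run, where ~2-sigma
coverage is meaningful; the generator default stays at three.

## Problem sizes

The verification suites run at desk scale: the enumeration oracle is
exercised on 100 random trees with ≤5 leaves (the exhaustive sum grows as
20^internal-nodes), parsimony against brute force on all topologies with
≤6 leaves, decay recovery on 50 seeded simulations per rate across
k ∈ {10⁻³, 10⁻², 10⁻¹, 1} min⁻¹, and the gel pipeline end to end at three
rates with eight lanes each. These sizes make every check exact or tightly
seeded while keeping the whole suite fast.
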