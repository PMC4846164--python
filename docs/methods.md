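# Methods

## The model

`rrscan` analyzes the configurational ensemble of a protein sampled by
molecular dynamics under the quasi-harmonic approximation: the distribution
of aligned Cartesian fluctuations is modelled as a multivariate Gaussian on
an effective harmonic potential. The force-constant matrix of that potential
is

    F = k_B T · C⁻¹,

where C is the 3N×3N covariance of the least-squares-fitted coordinates
(rotation and translation projected out by the fit). Effective vibrational
frequencies solve the secular equation det(F − ω²M) = 0 with M the diagonal
mass matrix, and the configurational entropy is the quantum-harmonic-
oscillator sum over the 3n−6 internal modes,

    S_config = k_B Σ_i [ x_i/(e^{x_i}−1) − ln(1−e^{−x_i}) ],   x_i = ħω_i/(k_B T).

S_config is an approximation of the target value: it is exact only within
the harmonic limit and includes no anharmonic or higher-order correlation
corrections (a deliberate non-goal).

In a rigid-residue scan (RRS), one residue at a time is treated as a rigid
body during simulation; the analysis side of that experiment — ΔS of the
whole protein relative to the unperturbed run, ΔΔS between bound and unbound
states with the same residue rigid, per-residue entropy responses, and
ensemble-shift projections — is what this package computes. Running the MD
itself is out of scope.

## Numerical route for the modes

The paper-facing definition inverts C, but C is structurally rank-deficient:
superposition nulls ≥ 6 directions, and whenever 3N exceeds the frame count
the sampled covariance is singular outright. We therefore diagonalize the
mass-weighted covariance

    σ = M^{1/2} C M^{1/2},   σ v_k = λ_k v_k,   ω_k = sqrt(k_B T / λ_k),

which needs no inverse and yields the same frequencies for full-rank C. That
equivalence is *asserted by a test* (σ-route vs explicit `scipy.linalg.eigh`
generalized solve of (F, M) on full-rank 5-atom systems, 10⁻⁸ relative), not
assumed.

Mode handling:

- modes with λ < 10⁻⁶·λ_max are treated as null directions and dropped;
- whole-protein scope drops at least the 6 smallest-λ modes (external
  translation/rotation remnants), matching the 3n−6 mode count;
- residue scope (below) drops none beyond tolerance;
- eigenvector signs are pinned (largest-magnitude component positive) for
  reproducible serialization; every overlap comparison is unsigned anyway.

Internal units are amu, Å, ps; k_B = 1.987204×10⁻³ kcal/(mol·K);
1 kcal/mol = 418.4 amu·Å²/ps²; frequencies are reported as ν̃ = ω/(2πc) in
cm⁻¹. Default temperature is 300 K, the usual NVT simulation temperature.

## Per-residue entropy decomposition

A residue's contribution is computed from its 3m×3m diagonal block of the
*whole-protein* covariance: the block is gathered as-is (the subsystem is
not re-aligned), processed through the same σ-route, and summed. Covariance
between the residue and the rest of the protein is excluded by construction,
so the decomposition is not additive for correlated residues — it is a
contribution measure, not a partition. By default no rigid-body modes are
removed from the block: the residue genuinely translates and rotates within
the aligned protein frame, and that motion carries entropy. Because the
original procedure is silent on this point, `residue_entropy` exposes
`remove_rigid_body_modes=True` as the alternative. Per-atom normalization
(S/m) is available to compare residues of different size.

A singular block (frozen residue) yields S = 0 with a warning rather than an
error, since that is the physically meaningful value.

## Covariance and cross-correlation

Covariance uses the population divisor F (immaterial at F = 15,000 but fixed
for bit-reproducibility) and a two-pass mean-then-deviation accumulation in
double precision. Cross-correlation is the trace of the 3×3 inter-atomic
block over the geometric mean of the atomic variances; motion along
orthogonal directions gives exactly 0. Atomic variance below 10⁻¹² Å² is
treated as zero and the affected entries are reported as NaN with a warning.
The default heat-map subset is Cα; all-atom is a flag. Hydrogens are kept if
the topology contains them (a flagged choice, since "all-atom" conventions
vary).

## Frame selection and fits

Frame k of a trajectory is timestamped (k+1)·Δt after its origin, and the
selection window is half-open: after discarding D ns, the first retained
frame sits at D + interval, so a 34 ns run with 4 ns discarded and 2 ps
sampling yields exactly 15,000 frames. All superpositions are mass-unweighted
all-atom Kabsch fits, matching the unweighted RMSD definition. `superpose`
(which must return a well-defined transform) rejects fewer than 3
non-collinear atoms; `rmsd_series` accepts degenerate structures because the
minimum RMSD value is still unique there.

The velocity-autocorrelation relaxation time is the first 1/e crossing of
the normalized VACF with linear interpolation between lag samples — chosen
because it is parameter-free; the integral definition is available via
`method="integral"` and should be used with a bounded `max_lag`, since the
statistical noise of the VACF tail otherwise dominates the running integral.

## Projections, coherence and ensemble distance

PCA contribution fractions are λ_k/Σλ over retained internal modes. Frame
projections are mass-weighted, p_k(t) = v_k·M^{1/2}(x(t) − ⟨x⟩), so the
variance of p_k is λ_k — a round-trip identity the tests check at 5% with
10⁴ frames.

A low-frequency mode is only trusted when independent trajectory blocks
reproduce it: `coherence_check` reports, per mode, the mean and SD of the
unsigned dot product between each block's mode and the full-run mode, plus
the all-pairs unsigned PC1 matrix among blocks. For a model with a spectral
gap the PC1 agreement approaches 1; for a degenerate (isotropic) model it
falls to the random-vector baseline E|u·v| = sqrt(2/(πd)).

Two states are compared by projecting both ensembles onto the pair of
state-specific PC1 axes about a common mean (the unperturbed reference
state's mean by convention). The axes are used as-is — *not*
Gram–Schmidt-orthogonalized — so the chart is oblique exactly as plotted in
the source analyses; the axis dot product is recorded on the cloud. The
"attraction basin" separation is implemented as the Euclidean distance
between cloud centroids (the original work never defines it); a 2D-histogram
peak distance is available via `method="density_mode"` for visibly
multimodal clouds. Projections are mass-weighted by default, consistent with
the modes; a plain-Cartesian flag exists.

## Scan bookkeeping and error bars

ΔS tables reference each state's own unperturbed run by default;
`reference_state=` switches to a single cross-state reference (both readings
of the published figure exist). ΔΔS(r) = S_bound(r) − S_unbound(r) including
r = 0, and the key-residue screen keeps residues with |ΔΔS(r)| strictly
below the unperturbed pair's |ΔΔS|, sorted ascending. Response maps are
S_j(run) − S_j(unperturbed) with the unperturbed row kept (zero by
construction); the self-rigid diagonal is strongly negative. The average
response includes the diagonal cell by default (matching a mean over all
rigid runs), with `include_diagonal=False` as the alternative.

Error bars for repeated-trajectory means use the two-sided Student-t
half-width t_{1−α/2,n−1}·sd/√n. The method was adopted because it reproduces
all sixteen published (σ → 85% CI) pairs for n = 7 trajectory blocks to
±0.001, which the test suite asserts. The published ΔΔS interval (σ 0.037 →
CI 0.039) is a difference-of-means quantity outside that formula and is not
asserted.

## The synthetic generator

`synthetic.build_enm_model` builds an isotropic-spring elastic-network
Hessian H from pairwise contacts (default cutoff 8 Å, spring
1 kcal/(mol·Å²)) and takes the classical equilibrium covariance
C = k_B T·H⁺, pseudo-inverse excluding the six exact zero modes. A
disconnected contact graph is rejected with a component report. The model's
spectrum and entropy are closed-form (self-consistent with `config_entropy`
by construction), so the pipeline can be checked end-to-end: sampling 15,000
frames and running covariance → modes → entropy recovers the analytic value
within 2% on the default toy (3 residues × 4 atoms on a coarse helix —
small enough for exhaustive oracles, large enough for residue sub-blocks).

`apply_rigid_residue` projects the residue's covariance block onto its ≤6
rigid-body directions (G C Gᵀ with G an orthogonal projector), keeping the
matrix PSD. This emulates the *analysis signature* of a rigid residue — the
rank-≤6 block and the diminished self-entropy ("blue diagonal") — but it is
a covariance-space construction, not a constrained integrator: it cannot
reproduce the re-equilibration effects by which real rigid-body MD often
*raises* total protein entropy elsewhere. That central empirical observation
of RRS simulations is therefore untestable here without an MD engine, and
passing tests say nothing about it.

`two_state_shift` displaces the mean by magnitude·M^{−1/2}·mode with the
covariance untouched — a pure population shift whose projected separation
equals the imposed magnitude, used to validate the 2D-distance machinery at
3·SE sampling tolerance.

What the generator does **not** emulate: anharmonicity, multi-basin
kinetics, solvent damping, sampling autocorrelation (frames are i.i.d.), or
force-field realism. Passing tests demonstrate the correctness of the
analysis chain, not the behaviour of real proteins.

## Problem sizes and determinism

Default validation sizes: 12-atom toy model, 15,000 frames for entropy
recovery, 10⁴ frames for projection/distance checks, 10⁵ frames for raw
sampling checks, 7 blocks × 3,000 frames for coherence. All random draws go
through `numpy.random.default_rng` with explicit seeds; reruns are
byte-identical. Sampling-statistics tolerances are stated per test (3–4.5
standard errors, family-wise where many elements are compared at once).

## Known limitations

- Entropy is harmonic-limit only; it systematically misstates systems with
  multiple occupied basins.
- The per-residue decomposition excludes inter-residue correlation entropy
  and does not sum to the whole-protein value unless residues are
  independent.
- The rigid-residue emulation is analytic, not dynamical (see above).
- `density_mode` distances are histogram-resolution-limited; the centroid
  distance is the defined quantity.
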