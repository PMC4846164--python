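# rrscan

Rigid-residue-scan (RRS) allostery analysis of molecular-dynamics ensembles:
quasi-harmonic configurational entropy, per-residue entropy decomposition,
coherent-mode PCA, and quantification of ensemble-distribution shifts
between ligation states.

## Who this is for

Computational structural biologists probing allosteric communication by
perturbation scanning: a family of MD simulations in which, one residue at a
time, a residue's internal degrees of freedom are frozen (held as a rigid
body), and the protein's response is read off as entropy and mode changes.
`rrscan` is the analysis side of that experiment — it consumes topologies
and trajectories (PDB/DCD/XTC, or plain-text atom tables and multi-model PDB
for small cases) and produces the scan-level statistics. It does not run MD.

## The model

Aligned Cartesian fluctuations are treated as a Gaussian on an effective
harmonic potential with force constants **F** = k_B T **C**⁻¹, where **C**
is the 3N×3N covariance of the least-squares-fitted coordinates. The
quasi-harmonic frequencies solve det(**F** − ω²**M**) = 0, and the
configurational entropy is the quantum-harmonic-oscillator sum over the
3n−6 internal modes:

    S_config = k_B Σ_i [ x_i/(e^{x_i}−1) − ln(1−e^{−x_i}) ],   x_i = ħω_i/(k_B T)

Numerically the package diagonalizes the mass-weighted covariance
σ = M^{1/2} C M^{1/2} (ω_k = sqrt(k_B T/λ_k)) instead of inverting the
rank-deficient C; the equivalence is test-asserted on full-rank systems.
On top of this sit: per-residue entropies from residue sub-covariance
blocks, ΔS/ΔΔS scan bookkeeping with a key-residue screen, Student-t error
bars for repeated trajectories, block-coherence validation of PC1, and 2D
projections of two states onto their (oblique) PC1 axes with a
centroid-distance separation measure. Details and all conventions:
[docs/methods.md](docs/methods.md).

A built-in synthetic module generates elastic-network harmonic ensembles
with closed-form entropy — including analytically rigidified residues and
two-state mean shifts — so every stage is validated against exact oracles.

## Worked example

Generate a 15,000-frame ensemble from the built-in 12-atom harmonic toy
model, then run the chain:

```console
$ rrscan simulate --frames 15000 --seed 11 --out-prefix toy
wrote toy_model.h5 and toy_traj.pdb (15000 frames, analytic S = 0.136378 kcal/(mol·K))

$ rrscan covar toy_traj.pdb --interval-ps 2
wrote covariance.h5 (3N = 36, F = 15000)

$ rrscan entropy toy_traj.pdb covariance.h5
S_config = 0.136399 kcal/(mol·K) over 30 modes (T = 300.0 K)

$ rrscan pca toy_traj.pdb covariance.h5
wrote spectrum.h5; 23 modes reach 90% of the dynamics (PC1 fraction 0.134, PC1 frequency 25.70 cm⁻¹)
```

Reading the numbers: the model's exact entropy is 0.136378 kcal/(mol·K);
the pipeline estimate from 15,000 sampled frames is 0.136399 — a 0.015%
error, i.e. the covariance → modes → entropy chain recovers the closed form
at the sampling depth used for 30 ns production trajectories. All 30
internal modes (3·12 − 6) are retained; the softest mode at 25.7 cm⁻¹
carries 13.4% of the total fluctuation variance, and 23 modes are needed to
reach 90% — low-frequency modes dominate the dynamics.

Scan bookkeeping for a real protein-sized run (94 residues, two ligation
states, 34 ns per job with 4 ns discarded, 2 ps frames):

```console
$ rrscan manifest --residues 94
190 jobs, 15000 frames/job, 5700 ns total analyzed
```

Other subcommands: `rmsd`, `residue-entropy`, `project`, `ledger`
(ΔS/ΔΔS tables and the key-residue screen from an entropy-ledger CSV); see
`rrscan --help`. The same functionality is available as a library
(`rrscan.run_pipeline` drives the whole chain over a scan).

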