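"""Quasi-harmonic modes, configurational entropy and density of states.

The sampled fluctuation distribution is modelled as a Gaussian on an
effective harmonic potential whose force constants are F = k_B T C⁻¹, with C
the aligned coordinate covariance. The normal modes then solve the secular
equation det(F − ω²M) = 0 with M the diagonal mass matrix. We solve the
mathematically equivalent symmetric problem instead: eigenvalues λ_k of the
mass-weighted covariance σ = M^{1/2} C M^{1/2} give ω_k = sqrt(k_B T / λ_k).
This avoids inverting C, which is rank-deficient whenever 3N exceeds the
frame count and always has ≥ 6 null directions after superposition; the
equivalence to the explicit C⁻¹ route is asserted by tests on full-rank toys,
not assumed.

Entropy is the quantum-harmonic-oscillator sum over retained modes,

    S = k_B Σ_i [ x_i/(e^{x_i}−1) − ln(1−e^{−x_i}) ],   x_i = ħω_i/(k_B T),

reported in kcal/(mol·K). For a whole protein the 3n−6 internal modes enter
(the 6 smallest-λ modes are external translation/rotation remnants and are
dropped); for a residue sub-block every above-tolerance mode is retained,
because the subsystem is never re-aligned and its rigid-body motion within
the protein is genuine configurational freedom of the residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import constants
from .correlation import CovarianceMatrix, residue_submatrix
from .trajectory_io import Topology

#: Modes with λ below this fraction of λ_max are treated as null directions.
MODE_DROP_TOL = 1e-6


@dataclass(frozen=True)
class QHSpectrum:
    """Quasi-harmonic frequencies (cm⁻¹, ascending) and mass-weighted modes.

    ``modes`` columns are orthonormal in mass-weighted coordinates and ordered
    to match ``frequencies`` (ascending frequency = descending variance λ).
    ``variances`` stores λ in amu·Å², the per-mode fluctuation variance.
    """

    frequencies: np.ndarray
    modes: np.ndarray
    variances: np.ndarray
    temperature: float
    n_dropped: int

    def __post_init__(self):
        freq = np.asarray(self.frequencies, dtype=float)
        lam = np.asarray(self.variances, dtype=float)
        if freq.size and (np.any(freq <= 0) or np.any(np.diff(freq) < -1e-9)):
            raise ValueError("frequencies must be strictly positive and ascending")
        if freq.shape != lam.shape:
            raise ValueError("frequencies and variances must align")
        object.__setattr__(self, "frequencies", freq)
        object.__setattr__(self, "variances", lam)
        object.__setattr__(self, "modes", np.asarray(self.modes, dtype=float))

    @property
    def n_modes(self) -> int:
        return self.frequencies.size


@dataclass(frozen=True)
class EntropyResult:
    """Configurational entropy in kcal/(mol·K)."""

    S: float
    n_modes_used: int
    temperature: float
    scope: str = "protein"
    normalized_per_atom: float | None = None


def _fix_mode_signs(modes: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component of each column positive.

    Eigenvector signs are arbitrary; this pins them for reproducible
    serialization. All overlap comparisons remain unsigned regardless.
    """
    if modes.size == 0:
        return modes
    top = np.argmax(np.abs(modes), axis=0)
    signs = np.sign(modes[top, np.arange(modes.shape[1])])
    signs[signs == 0] = 1.0
    return modes * signs


def qh_modes(cov: CovarianceMatrix, topology: Topology, temperature: float = constants.DEFAULT_TEMPERATURE,
             n_external: int = 6, drop_tol: float = MODE_DROP_TOL) -> QHSpectrum:
    """Quasi-harmonic spectrum from a covariance via σ = M^{1/2} C M^{1/2}.

    ``n_external`` forces at least that many smallest-λ modes out regardless
    of tolerance (6 for whole-protein scope; 0 for residue sub-blocks).
    """
    if topology.n_atoms != cov.n_atoms:
        raise ValueError("topology/covariance atom count mismatch")
    sqrt_m = np.sqrt(np.repeat(topology.atom_masses[cov.atom_order], 3))
    sigma = cov.matrix * np.outer(sqrt_m, sqrt_m)
    lam, vec = np.linalg.eigh(sigma)  # ascending
    lam_max = lam[-1] if lam.size else 0.0
    if lam_max <= 0:
        raise ValueError("covariance has no positive fluctuation modes")
    if lam[0] < -drop_tol * lam_max:
        raise ValueError(f"covariance has a significantly negative eigenvalue ({lam[0]:.3e})")
    n_below = int(np.sum(lam < drop_tol * lam_max))
    n_drop = max(n_below, int(n_external))
    if n_drop >= lam.size:
        raise ValueError("all quasi-harmonic modes fall below tolerance")
    lam_keep = lam[n_drop:][::-1]  # descending λ = ascending ω
    vec_keep = vec[:, n_drop:][:, ::-1]
    kbt = constants.kbt_internal(temperature)
    omega = np.sqrt(kbt / lam_keep)  # rad/ps
    return QHSpectrum(
        frequencies=np.asarray(constants.omega_to_wavenumber(omega)),
        modes=_fix_mode_signs(vec_keep),
        variances=lam_keep,
        temperature=temperature,
        n_dropped=n_drop,
    )


def mode_entropies(frequencies_cm1: np.ndarray, temperature: float) -> np.ndarray:
    """Per-mode QHO entropy contribution, kcal/(mol·K)."""
    omega = np.asarray(constants.wavenumber_to_omega(np.asarray(frequencies_cm1, dtype=float)))
    x = constants.HBAR_KCAL_PS * omega / (constants.KB_KCAL * temperature)
    with np.errstate(over="ignore", divide="ignore"):
        term = x / np.expm1(x) - np.log(-np.expm1(-x))
    return constants.KB_KCAL * np.where(np.isfinite(term), term, 0.0)


def config_entropy(spectrum: QHSpectrum, scope: str = "protein") -> EntropyResult:
    """QHO configurational entropy summed over the spectrum's retained modes."""
    if spectrum.n_modes == 0:
        raise ValueError("empty spectrum")
    if np.any(spectrum.frequencies <= 0):
        raise ValueError("retained frequencies must be positive")
    s = float(np.sum(mode_entropies(spectrum.frequencies, spectrum.temperature)))
    return EntropyResult(S=s, n_modes_used=spectrum.n_modes,
                         temperature=spectrum.temperature, scope=scope)


def residue_entropy(cov: CovarianceMatrix, topology: Topology, resid: int,
                    temperature: float = constants.DEFAULT_TEMPERATURE,
                    remove_rigid_body_modes: bool = False) -> EntropyResult:
    """Entropy of one residue from its 3m×3m sub-covariance block.

    The block is processed exactly like a whole-protein covariance except
    that, by default, no external modes are removed: correlation with the
    rest of the protein is excluded by construction, but the residue's
    rigid-body motion inside the (aligned) protein frame is real and kept.
    Set ``remove_rigid_body_modes`` to drop the 6 smallest-λ block modes too.
    """
    sub = residue_submatrix(cov, topology, resid)
    sub_top = Topology(
        atom_ids=np.arange(1, sub.atom_order.size + 1),
        atom_masses=topology.atom_masses[sub.atom_order],
        residue_index=np.ones(sub.atom_order.size, dtype=int),
    )
    sub = CovarianceMatrix(sub.matrix, atom_order=np.arange(sub.atom_order.size),
                           n_frames_used=sub.n_frames_used, aligned=sub.aligned)
    n_ext = 6 if remove_rigid_body_modes else 0
    try:
        spec = qh_modes(sub, sub_top, temperature, n_external=n_ext)
    except ValueError:
        warnings.warn(f"residue {resid}: no quasi-harmonic modes above tolerance; "
                      "reporting S = 0")
        return EntropyResult(S=0.0, n_modes_used=0, temperature=temperature,
                             scope=f"residue:{resid}")
    return config_entropy(spec, scope=f"residue:{resid}")


def normalize_residue_entropy(result: EntropyResult, topology: Topology) -> EntropyResult:
    """Divide a residue entropy by its atom count (per-atom normalization)."""
    if not result.scope.startswith("residue:"):
        raise ValueError("normalization applies to residue-scope results")
    resid = int(result.scope.split(":", 1)[1])
    m = topology.residue_atoms(resid).size
    return EntropyResult(S=result.S, n_modes_used=result.n_modes_used,
                         temperature=result.temperature, scope=result.scope,
                         normalized_per_atom=result.S / m)


def density_of_states(spectrum: QHSpectrum, bin_width: float):
    """Histogram of retained frequencies; bin edges start at 0.

    Returns (counts, edges); counts sum to the number of retained modes.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if spectrum.n_modes == 0:
        raise ValueError("empty spectrum")
    top = np.ceil(spectrum.frequencies.max() / bin_width) * bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges[-1] < spectrum.frequencies.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(spectrum.frequencies, bins=edges)
    return counts, edges
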