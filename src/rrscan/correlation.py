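"""All-atom covariance and normalized cross-correlation matrices.

The 3N×3N coordinate covariance is the object the whole quasi-harmonic
machinery is built on: its inverse (scaled by k_B T) is the effective force
constant matrix, and its per-residue diagonal blocks carry the residue
entropy decomposition. Covariance is accumulated two-pass (mean first, then
deviations) in double precision, with the population divisor F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trajectory_io import FrameEnsemble, Topology

#: Variance below this (Å²) is treated as exactly zero.
ZERO_VARIANCE_TOL = 1e-12


@dataclass(frozen=True)
class CovarianceMatrix:
    """Symmetric PSD 3N×3N coordinate covariance (Å²)."""

    matrix: np.ndarray
    atom_order: np.ndarray
    n_frames_used: int
    aligned: bool = True

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] % 3:
            raise ValueError("covariance must be square with 3N rows")
        if not np.allclose(m, m.T, atol=1e-8 * max(1.0, np.abs(m).max())):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "atom_order", np.asarray(self.atom_order, dtype=int))

    @property
    def n_atoms(self) -> int:
        return self.matrix.shape[0] // 3


@dataclass(frozen=True)
class CrossCorrelationMatrix:
    """N×N normalized cross-correlation; entries in [−1, 1], diagonal 1."""

    matrix: np.ndarray
    atom_subset: np.ndarray


def covariance_matrix(ensemble: FrameEnsemble) -> CovarianceMatrix:
    """Population covariance of the flattened coordinates of an aligned ensemble."""
    if not ensemble.is_aligned:
        raise ValueError("covariance requires a superposed ensemble (rigid-body "
                         "motion must be projected out by fitting first)")
    f = ensemble.n_frames
    if f < 2:
        raise ValueError("need at least 2 frames")
    x = ensemble.coordinates.reshape(f, -1)
    dev = x - x.mean(axis=0)
    cov = dev.T @ dev / f
    cov = 0.5 * (cov + cov.T)
    return CovarianceMatrix(cov, atom_order=np.arange(ensemble.n_atoms),
                            n_frames_used=f, aligned=True)


def _resolve_subset(topology: Topology, subset) -> np.ndarray:
    if subset is None or (isinstance(subset, str) and subset.lower() == "all"):
        return np.arange(topology.n_atoms)
    if isinstance(subset, str):
        if subset.upper() in ("CA", "CALPHA"):
            if topology.atom_names is None:
                raise ValueError("Cα selection needs atom names in the topology")
            idx = np.flatnonzero(np.char.upper(
                topology.atom_names.astype(str)) == "CA")
            if idx.size == 0:
                raise ValueError("topology contains no CA atoms")
            return idx
        raise ValueError(f"unknown atom subset {subset!r}")
    return np.asarray(subset, dtype=int)


def cross_correlation(cov: CovarianceMatrix, topology: Topology,
                      subset="CA") -> CrossCorrelationMatrix:
    """Normalized covariance C_ij = tr(cov block ij) / sqrt(tr_ii · tr_jj).

    +1 is fully correlated motion, −1 anti-correlated; motion along orthogonal
    directions gives 0. Zero-variance atoms yield NaN entries with a warning.
    """
    idx = _resolve_subset(topology, subset)
    m = len(idx)
    blocks = cov.matrix.reshape(cov.n_atoms, 3, cov.n_atoms, 3)
    inner = np.einsum("iaja->ij", blocks[idx][:, :, idx, :])  # tr of 3×3 blocks
    var = np.diag(inner).copy()
    bad = var < ZERO_VARIANCE_TOL
    if np.any(bad):
        warnings.warn(f"{bad.sum()} subset atom(s) have (near-)zero variance; "
                      "their cross-correlations are undefined (NaN)")
        var[bad] = np.nan
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore"):
        corr = inner / denom
        corr = np.clip(corr, -1.0, 1.0)
    corr[np.arange(m), np.arange(m)] = np.where(bad, np.nan, 1.0)
    return CrossCorrelationMatrix(corr, atom_subset=idx)


def residue_submatrix(cov: CovarianceMatrix, topology: Topology,
                      resid: int) -> CovarianceMatrix:
    """The residue's 3m×3m diagonal block of the whole-protein covariance.

    Rows/columns are simply gathered: the subsystem is deliberately NOT
    re-aligned, and covariance with atoms outside the residue is excluded.
    """
    if topology.n_atoms != cov.n_atoms:
        raise ValueError("topology/covariance atom count mismatch")
    atoms = topology.residue_atoms(resid)
    ci = topology.coordinate_indices(resid)
    sub = cov.matrix[np.ix_(ci, ci)]
    return CovarianceMatrix(sub, atom_order=atoms, n_frames_used=cov.n_frames_used,
                            aligned=cov.aligned)
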