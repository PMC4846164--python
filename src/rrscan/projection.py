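"""PCA contributions, mode coherence across trajectory blocks, 2D projections.

The lowest-frequency (largest-variance) quasi-harmonic mode, PC1, is only
trusted as a physical "coherent mode" when independent trajectory blocks keep
producing essentially the same vector; the coherence check quantifies that
with unsigned dot products (eigenvector signs are arbitrary). Two states'
PC1 vectors then span an oblique 2D chart on which the unbound and bound
ensembles can be compared as point clouds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quasiharmonic import QHSpectrum
from .trajectory_io import FrameEnsemble, Topology

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class ModeOverlapReport:
    """Signed dot products between two mode sets plus unsigned summaries."""

    dot_matrix: np.ndarray       # |A| × |B| signed dot products
    unsigned_mean: np.ndarray    # per matched mode, mean |dot|
    unsigned_sd: np.ndarray


@dataclass(frozen=True)
class CoherenceReport:
    """Block-vs-full mode agreement (per mode) and PC1 block-pair agreement."""

    block_dots: np.ndarray        # n_blocks × k signed dots, block_k · full_k
    unsigned_mean: np.ndarray     # per mode over blocks
    unsigned_sd: np.ndarray
    pc1_pair_matrix: np.ndarray   # n_blocks × n_blocks signed PC1 dots
    pc1_offdiag_mean: float
    pc1_offdiag_sd: float


@dataclass(frozen=True)
class ProjectionCloud:
    """F×2 projections of frames onto a pair of PC1 axes."""

    points: np.ndarray
    state_label: str
    run_id: str = ""
    axis_dot: float = float("nan")

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be F×2")
        if pts.shape[0] == 0:
            raise ValueError("empty projection cloud")
        object.__setattr__(self, "points", pts)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def pca_contributions(spectrum: QHSpectrum, threshold: float = 0.90):
    """Per-mode variance fractions λ_k/Σλ, cumulative sum, and the smallest
    mode count whose cumulative contribution reaches ``threshold``.

    Translational/rotational modes were already excluded when the spectrum
    was built, so the fractions cover internal dynamics only.
    """
    lam = spectrum.variances
    if lam.size == 0:
        raise ValueError("empty spectrum")
    fractions = lam / lam.sum()
    cumulative = np.cumsum(fractions)
    n_to_threshold = int(np.searchsorted(cumulative, threshold - 1e-12) + 1)
    return fractions, cumulative, n_to_threshold


def _mass_weights(topology: Topology) -> np.ndarray:
    return np.sqrt(np.repeat(topology.atom_masses, 3))


def project_frames(ensemble: FrameEnsemble, spectrum: QHSpectrum,
                   mode_ids, topology: Topology,
                   mean_structure: np.ndarray | None = None) -> np.ndarray:
    """Project frames onto modes: p_k(t) = mode_k · M^{1/2}(x(t) − ⟨x⟩).

    Returns an F × len(mode_ids) array (units Å·amu^{1/2}); each column has
    mean ≈ 0 when the ensemble mean is the reference.
    """
    mode_ids = np.asarray(mode_ids, dtype=int)
    x = ensemble.coordinates.reshape(ensemble.n_frames, -1)
    if spectrum.modes.shape[0] != x.shape[1]:
        raise ValueError("mode dimensionality does not match the ensemble")
    mean = x.mean(axis=0) if mean_structure is None \
        else np.asarray(mean_structure, dtype=float).reshape(-1)
    dev = (x - mean) * _mass_weights(topology)
    return dev @ spectrum.modes[:, mode_ids]


def _check_unit(vectors: np.ndarray, name: str) -> None:
    norms = np.linalg.norm(vectors, axis=0)
    if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
        raise ValueError(f"{name} must be unit-norm (norms {norms})")


def mode_overlap(modes_a: np.ndarray, modes_b: np.ndarray) -> ModeOverlapReport:
    """Signed dot-product matrix between two unit-norm mode sets.

    The unsigned summaries are per matched (diagonal) mode; with a single
    set pair each mode contributes one |dot|, so the SD is zero.
    """
    a = np.atleast_2d(np.asarray(modes_a, dtype=float))
    b = np.atleast_2d(np.asarray(modes_b, dtype=float))
    if a.shape[0] == 1:
        a = a.T
    if b.shape[0] == 1:
        b = b.T
    if a.shape[0] != b.shape[0]:
        raise ValueError("mode sets live in different dimensions")
    _check_unit(a, "modes_a")
    _check_unit(b, "modes_b")
    dots = a.T @ b
    k = min(dots.shape)
    diag = np.abs(np.diagonal(dots)[:k])
    return ModeOverlapReport(dot_matrix=dots, unsigned_mean=diag,
                             unsigned_sd=np.zeros(k))


def coherence_check(block_spectra: list[QHSpectrum], full_spectrum: QHSpectrum,
                    k_modes: int = 5) -> CoherenceReport:
    """How reproducible are the low-frequency modes across trajectory blocks?

    For each of the ``k_modes`` largest-variance modes, collects the signed
    dot product of every block's mode with the full-trajectory mode and
    summarizes |dot| (mean, SD) per mode. Also returns the all-pairs signed
    PC1 dot matrix among the blocks themselves.
    """
    if len(block_spectra) < 2:
        raise ValueError("need at least 2 trajectory blocks")
    dim = full_spectrum.modes.shape[0]
    for spec in block_spectra:
        if spec.modes.shape[0] != dim:
            raise ValueError("blocks use differing atom sets")
    full = full_spectrum.modes[:, :k_modes]
    rows = []
    for spec in block_spectra:
        rows.append(np.einsum("dk,dk->k", spec.modes[:, :k_modes], full))
    block_dots = np.array(rows)
    pc1 = np.array([spec.modes[:, 0] for spec in block_spectra])
    pc1_pairs = pc1 @ pc1.T
    off = np.abs(pc1_pairs[~np.eye(len(block_spectra), dtype=bool)])
    return CoherenceReport(
        block_dots=block_dots,
        unsigned_mean=np.abs(block_dots).mean(axis=0),
        unsigned_sd=np.abs(block_dots).std(axis=0, ddof=1),
        pc1_pair_matrix=pc1_pairs,
        pc1_offdiag_mean=float(off.mean()),
        pc1_offdiag_sd=float(off.std(ddof=1)),
    )


def project_2d(ensemble: FrameEnsemble, pc1_state_a: np.ndarray,
               pc1_state_b: np.ndarray, common_mean: np.ndarray,
               topology: Topology, state_label: str = "", run_id: str = "",
               mass_weighted: bool = True) -> ProjectionCloud:
    """Project frames onto the (PC1_a, PC1_b) plane about a common mean.

    The two axes are used as-is — they are generally oblique (for the PDZ-like
    use case nearly orthogonal) and are deliberately NOT re-orthogonalized, so
    distances live in the same oblique chart as the published 2D maps.
    """
    a = np.asarray(pc1_state_a, dtype=float).reshape(-1)
    b = np.asarray(pc1_state_b, dtype=float).reshape(-1)
    _check_unit(a[:, None], "pc1_state_a")
    _check_unit(b[:, None], "pc1_state_b")
    x = ensemble.coordinates.reshape(ensemble.n_frames, -1)
    if a.size != x.shape[1] or b.size != x.shape[1]:
        raise ValueError("axis dimensionality does not match the ensemble")
    dev = x - np.asarray(common_mean, dtype=float).reshape(-1)
    if mass_weighted:
        dev = dev * _mass_weights(topology)
    pts = np.column_stack([dev @ a, dev @ b])
    return ProjectionCloud(points=pts, state_label=state_label, run_id=run_id,
                           axis_dot=float(a @ b))


def distribution_distance(cloud_a: ProjectionCloud, cloud_b: ProjectionCloud,
                          method: str = "centroid", bins: int = 40) -> float:
    """Separation between two projected ensembles on the shared 2D chart.

    ``centroid`` (default): Euclidean distance between cloud centroids.
    ``density_mode``: distance between the peaks of 2D histograms — a crude
    "attraction basin" locator for visibly multimodal clouds.
    """
    if method == "centroid":
        return float(np.linalg.norm(cloud_a.centroid - cloud_b.centroid))
    if method == "density_mode":
        lo = np.minimum(cloud_a.points.min(axis=0), cloud_b.points.min(axis=0))
        hi = np.maximum(cloud_a.points.max(axis=0), cloud_b.points.max(axis=0))
        peaks = []
        for cloud in (cloud_a, cloud_b):
            h, xe, ye = np.histogram2d(cloud.points[:, 0], cloud.points[:, 1],
                                       bins=bins, range=[(lo[0], hi[0]), (lo[1], hi[1])])
            i, j = np.unravel_index(np.argmax(h), h.shape)
            peaks.append([(xe[i] + xe[i + 1]) / 2, (ye[j] + ye[j + 1]) / 2])
        return float(np.linalg.norm(np.subtract(*peaks)))
    raise ValueError(f"unknown distance method {method!r}")
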