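"""Trajectory ingestion, frame selection, superposition, RMSD and VACF.

Readers are thin wrappers over MDAnalysis: topology from PDB ATOM records
(masses from the element lookup) or a plain-text atom table; coordinates from
DCD, XTC or multi-model PDB. All fits are mass-unweighted all-atom
least-squares (Kabsch), matching the plain RMSD definition
R = sqrt(Σ_i |r_i⁰ − U r_i|² / N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Topology:
    """Atom identities, masses (amu) and 1-based residue membership."""

    atom_ids: np.ndarray
    atom_masses: np.ndarray
    residue_index: np.ndarray
    atom_names: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "atom_ids", np.asarray(self.atom_ids, dtype=int))
        object.__setattr__(self, "atom_masses", np.asarray(self.atom_masses, dtype=float))
        object.__setattr__(self, "residue_index", np.asarray(self.residue_index, dtype=int))
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", np.asarray(self.atom_names, dtype=object))
        n = self.atom_ids.size
        if self.atom_masses.shape != (n,) or self.residue_index.shape != (n,):
            raise ValueError("atom_ids, atom_masses and residue_index must have equal length")
        if np.any(self.atom_masses <= 0):
            raise ValueError("atom masses must be strictly positive")
        resids = np.unique(self.residue_index)
        if resids.size and (resids[0] < 1 or np.any(np.diff(resids) != 1)):
            raise ValueError("residue indices must be 1-based and contiguous")

    @property
    def n_atoms(self) -> int:
        return self.atom_ids.size

    @property
    def residue_count(self) -> int:
        return int(np.unique(self.residue_index).size)

    def residue_atoms(self, resid: int) -> np.ndarray:
        """Indices (0-based, into atom order) of the atoms of one residue."""
        idx = np.flatnonzero(self.residue_index == resid)
        if idx.size == 0:
            raise KeyError(f"unknown residue id {resid}")
        return idx

    def coordinate_indices(self, resid: int) -> np.ndarray:
        """The 3m Cartesian coordinate indices of one residue."""
        atoms = self.residue_atoms(resid)
        return (atoms[:, None] * 3 + np.arange(3)).ravel()


@dataclass(frozen=True)
class FrameEnsemble:
    """F×N×3 Cartesian coordinates (Å) with timing metadata.

    Frame k is taken at origin_time + (k+1)·frame_interval, so an interval of
    2 ps over 30 ns yields exactly 15,000 frames.
    """

    coordinates: np.ndarray
    frame_interval: float  # ps
    origin_time: float = 0.0  # ns
    aligned_to: str = "none"

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coordinates must have shape (F, N, 3)")
        if coords.shape[0] < 1:
            raise ValueError("at least one frame required")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates contain non-finite values")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        """Absolute frame times in ps."""
        return self.origin_time * 1000.0 + (np.arange(self.n_frames) + 1) * self.frame_interval

    @property
    def is_aligned(self) -> bool:
        return self.aligned_to != "none"


@dataclass(frozen=True)
class VelocitySeries:
    """F×N×3 atomic velocities (Å/ps)."""

    velocities: np.ndarray
    frame_interval: float  # ps

    def __post_init__(self):
        vel = np.asarray(self.velocities, dtype=float)
        if vel.ndim != 3 or vel.shape[2] != 3:
            raise ValueError("velocities must have shape (F, N, 3)")
        if not np.all(np.isfinite(vel)):
            raise ValueError("velocities contain non-finite values")
        object.__setattr__(self, "velocities", vel)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_topology(path: str) -> Topology:
    """Read a topology from a PDB file or a plain-text atom table.

    The atom table is whitespace- or comma-separated with columns
    ``id element mass resid`` (header optional).
    """
    if str(path).lower().endswith(".pdb"):
        return _topology_from_pdb(path)
    return _topology_from_table(path)


def _topology_from_pdb(path: str) -> Topology:
    import MDAnalysis as mda
    from MDAnalysis.topology.guessers import guess_masses, guess_types

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
        atoms = u.atoms
        try:
            masses = atoms.masses.copy()
        except mda.exceptions.NoDataError:
            masses = guess_masses(guess_types(atoms.names))
        if np.any(masses <= 0):
            bad = masses <= 0
            masses[bad] = guess_masses(guess_types(atoms.names[bad]))
    resids = atoms.resids - atoms.resids.min() + 1
    return Topology(
        atom_ids=np.arange(1, len(atoms) + 1),
        atom_masses=masses,
        residue_index=resids,
        atom_names=atoms.names,
    )


def _topology_from_table(path: str) -> Topology:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if not {"id", "mass", "resid"} <= set(cols):
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                         names=["id", "element", "mass", "resid"])
        cols = {c: c for c in df.columns}
    names = df[cols["element"]].to_numpy() if "element" in cols else None
    return Topology(
        atom_ids=df[cols["id"]].to_numpy(),
        atom_masses=df[cols["mass"]].to_numpy(),
        residue_index=df[cols["resid"]].to_numpy(),
        atom_names=names,
    )


def load_ensemble(topology_path: str, trajectory_path: str | None = None,
                  frame_interval: float = 2.0, origin_time: float = 0.0) -> FrameEnsemble:
    """Read coordinates (DCD/XTC/multi-model PDB) into a FrameEnsemble."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is None:
            u = mda.Universe(topology_path)
        else:
            u = mda.Universe(topology_path, trajectory_path)
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    return FrameEnsemble(coords, frame_interval=frame_interval, origin_time=origin_time)


def write_ensemble(ensemble: FrameEnsemble, topology: Topology, path: str) -> None:
    """Write an ensemble as a multi-model PDB or DCD (by extension)."""
    import MDAnalysis as mda

    n = topology.n_atoms
    u = mda.Universe.empty(n, n_residues=topology.residue_count,
                           atom_resindex=topology.residue_index - 1,
                           trajectory=True)
    u.add_TopologyAttr("masses", topology.atom_masses)
    names = topology.atom_names if topology.atom_names is not None else ["C"] * n
    u.add_TopologyAttr("names", [str(x) for x in names])
    u.add_TopologyAttr("resids", np.arange(1, topology.residue_count + 1))
    u.load_new(ensemble.coordinates.astype(np.float32), order="fac")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# frame selection
# ---------------------------------------------------------------------------

def select_frames(ensemble: FrameEnsemble, discard: float, interval: float) -> FrameEnsemble:
    """Drop an equilibration window and resample at a coarser interval.

    ``discard`` is in ns, ``interval`` in ps. The window is half-open: the
    first retained frame sits at discard + interval, so 30 ns at 2 ps gives
    15,000 frames. ``interval`` must be a positive multiple of the stored
    frame spacing.
    """
    dt = ensemble.frame_interval
    if interval <= 0:
        raise ValueError("interval must be positive")
    stride = interval / dt
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError(
            f"interval {interval} ps is not commensurate with the stored frame "
            f"spacing {dt} ps")
    discard_ps = discard * 1000.0
    total_ps = ensemble.n_frames * dt
    if discard_ps >= total_ps:
        raise ValueError(f"discard window ({discard} ns) leaves no frames "
                         f"(trajectory spans {total_ps / 1000.0} ns)")
    rel = (np.arange(ensemble.n_frames) + 1) * dt  # time since origin
    keep = (rel > discard_ps + 1e-9) & (
        np.abs((rel - discard_ps) / interval - np.round((rel - discard_ps) / interval)) < 1e-9)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("no frames remain after discard/resampling")
    return FrameEnsemble(
        ensemble.coordinates[idx],
        frame_interval=interval,
        origin_time=ensemble.origin_time + discard,
        aligned_to=ensemble.aligned_to,
    )


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

def _kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (SVD route) mapping centred mobile onto centred reference."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    return u @ corr @ vt


def _check_fittable(reference: np.ndarray) -> None:
    if reference.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    centred = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-10) < 2:
        raise ValueError("reference atoms are collinear; fit rotation is undefined")


def superpose(ensemble: FrameEnsemble, reference: np.ndarray,
              label: str = "reference") -> FrameEnsemble:
    """Least-squares fit every frame onto ``reference`` (N×3), unweighted."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (ensemble.n_atoms, 3):
        raise ValueError("reference atom count must match the ensemble")
    _check_fittable(reference)
    ref_centred = reference - reference.mean(axis=0)
    out = np.empty_like(ensemble.coordinates)
    for k in range(ensemble.n_frames):
        frame = ensemble.coordinates[k]
        mob = frame - frame.mean(axis=0)
        rot = _kabsch_rotation(mob, ref_centred)
        out[k] = mob @ rot + reference.mean(axis=0)
    return replace(ensemble, coordinates=out, aligned_to=label)


def rmsd_series(ensemble: FrameEnsemble, reference: np.ndarray) -> np.ndarray:
    """Per-frame best-fit RMSD (Å) to ``reference``: sqrt(Σ|r⁰−Ur|²/N).

    Unlike :func:`superpose`, degenerate (collinear or 2-atom) structures are
    accepted: the optimal rotation is then not unique, but the minimum RMSD
    value still is, and the Kabsch solution attains it.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (ensemble.n_atoms, 3):
        raise ValueError("reference atom count must match the ensemble")
    ref_centred = reference - reference.mean(axis=0)
    out = np.empty(ensemble.n_frames)
    for k in range(ensemble.n_frames):
        frame = ensemble.coordinates[k]
        mob = frame - frame.mean(axis=0)
        rot = _kabsch_rotation(mob, ref_centred)
        diff = mob @ rot - ref_centred
        out[k] = np.sqrt(np.mean(np.sum(diff * diff, axis=1)))
    return out


def rmsd_to_frame(a: np.ndarray, b: np.ndarray) -> float:
    """Best-fit RMSD between two single structures."""
    ens = FrameEnsemble(np.asarray(a, dtype=float)[None], frame_interval=1.0)
    return float(rmsd_series(ens, b)[0])


def average_structure(ensemble: FrameEnsemble) -> np.ndarray:
    """Per-atom arithmetic mean coordinates of an aligned ensemble."""
    if not ensemble.is_aligned:
        raise ValueError("ensemble must be superposed before averaging; the mean of "
                         "unaligned frames is meaningless")
    return ensemble.coordinates.mean(axis=0)


# ---------------------------------------------------------------------------
# velocity autocorrelation
# ---------------------------------------------------------------------------

def velocity_autocorrelation(vel: VelocitySeries, max_lag: int | None = None,
                             method: str = "crossing",
                             atom_subset: np.ndarray | None = None):
    """Normalized VACF and its relaxation time.

    VACF(τ) = ⟨v(t)·v(t+τ)⟩, averaged over atoms and time origins, scaled so
    VACF(0) = 1. The relaxation time is the first 1/e crossing (linear
    interpolation between lag samples); ``method="integral"`` instead returns
    the trapezoidal integral of the VACF over the computed lags.
    """
    v = vel.velocities
    if atom_subset is not None:
        v = v[:, np.asarray(atom_subset, dtype=int), :]
    f = v.shape[0]
    if f < 2:
        raise ValueError("need at least 2 frames for a velocity autocorrelation")
    if max_lag is None:
        max_lag = f // 2
    max_lag = min(max_lag, f - 1)
    flat = v.reshape(f, -1)
    vacf = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        vacf[tau] = np.mean(np.sum(flat[: f - tau] * flat[tau:], axis=1))
    if vacf[0] <= 0:
        raise ValueError("zero velocities: VACF normalization undefined")
    vacf = vacf / vacf[0]
    dt = vel.frame_interval
    lags = np.arange(max_lag + 1) * dt

    if method == "integral":
        return vacf, float(np.trapezoid(vacf, lags))
    if method != "crossing":
        raise ValueError(f"unknown relaxation-time method {method!r}")
    thresh = 1.0 / np.e
    below = np.flatnonzero(vacf <= thresh)
    if below.size == 0:
        warnings.warn("VACF never decays below 1/e over the computed lags")
        return vacf, float("nan")
    k = below[0]
    if k == 0:
        return vacf, 0.0
    # linear interpolation between samples k-1 and k
    frac = (vacf[k - 1] - thresh) / (vacf[k - 1] - vacf[k])
    return vacf, float(lags[k - 1] + frac * dt)


def series_to_csv(times_ps: np.ndarray, values: np.ndarray, path: str,
                  value_name: str = "value") -> None:
    """Tidy CSV export (frame_time_ps, value)."""
    pd.DataFrame({"frame_time_ps": times_ps, value_name: values}).to_csv(path, index=False)
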