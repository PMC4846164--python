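"""HDF5/CSV persistence for matrices, spectra and models."""

from __future__ import annotations

import numpy as np
import h5py

from .correlation import CovarianceMatrix
from .quasiharmonic import QHSpectrum
from .synthetic import HarmonicModel
from .trajectory_io import Topology


def save_covariance(cov: CovarianceMatrix, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("matrix", data=cov.matrix)
        fh.create_dataset("atom_order", data=cov.atom_order)
        fh.attrs["n_frames_used"] = cov.n_frames_used
        fh.attrs["aligned"] = cov.aligned


def load_covariance(path: str) -> CovarianceMatrix:
    with h5py.File(path, "r") as fh:
        return CovarianceMatrix(
            matrix=fh["matrix"][()],
            atom_order=fh["atom_order"][()],
            n_frames_used=int(fh.attrs["n_frames_used"]),
            aligned=bool(fh.attrs["aligned"]),
        )


def save_spectrum(spec: QHSpectrum, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("frequencies_cm1", data=spec.frequencies)
        fh.create_dataset("modes", data=spec.modes)
        fh.create_dataset("variances", data=spec.variances)
        fh.attrs["temperature"] = spec.temperature
        fh.attrs["n_dropped"] = spec.n_dropped


def load_spectrum(path: str) -> QHSpectrum:
    with h5py.File(path, "r") as fh:
        return QHSpectrum(
            frequencies=fh["frequencies_cm1"][()],
            modes=fh["modes"][()],
            variances=fh["variances"][()],
            temperature=float(fh.attrs["temperature"]),
            n_dropped=int(fh.attrs["n_dropped"]),
        )


def save_model(model: HarmonicModel, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("mean_structure", data=model.mean_structure)
        fh.create_dataset("covariance", data=model.covariance)
        fh.create_dataset("masses", data=model.topology.atom_masses)
        fh.create_dataset("residue_index", data=model.topology.residue_index)
        fh.attrs["temperature"] = model.temperature


def load_model(path: str) -> HarmonicModel:
    with h5py.File(path, "r") as fh:
        masses = fh["masses"][()]
        top = Topology(atom_ids=np.arange(1, masses.size + 1),
                       atom_masses=masses,
                       residue_index=fh["residue_index"][()])
        return HarmonicModel(
            topology=top,
            mean_structure=fh["mean_structure"][()],
            covariance=fh["covariance"][()],
            temperature=float(fh.attrs["temperature"]),
        )
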