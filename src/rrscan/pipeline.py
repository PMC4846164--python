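"""End-to-end orchestration: frames → covariance → entropy → PCA → ledgers.

``run_pipeline`` executes the full analysis chain for a set of runs (one per
(state, rigid_residue) pair) and writes every artifact with provenance
(config, seed, package version) so a rerun with the same inputs is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, constants
from .correlation import covariance_matrix
from .ledger import EntropyLedger, delta_delta_entropy, delta_entropy
from .projection import pca_contributions
from .quasiharmonic import config_entropy, qh_modes, residue_entropy
from .trajectory_io import FrameEnsemble, Topology, select_frames, superpose
from .persist import save_spectrum


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline settings, fully serialized into output metadata."""

    temperature: float = constants.DEFAULT_TEMPERATURE
    discard_ns: float = 0.0
    interval_ps: float | None = None  # None: keep the stored frame spacing
    subset: str = "CA"
    mode_drop_tol: float = 1e-6
    seed: int = 0
    output_dir: str = "rrscan_out"

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.discard_ns < 0:
            raise ValueError("discard_ns must be non-negative")
        if self.interval_ps is not None and self.interval_ps <= 0:
            raise ValueError("interval_ps must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def analyze_run(ensemble: FrameEnsemble, topology: Topology, config: RunConfig):
    """Single-run analysis: select/superpose/covariance/entropy/per-residue.

    Returns (total EntropyResult, per-residue S vector, QHSpectrum, frames used).
    """
    ens = ensemble
    if config.discard_ns > 0 or config.interval_ps is not None:
        ens = select_frames(ens, config.discard_ns,
                            config.interval_ps or ens.frame_interval)
    ens = superpose(ens, ens.coordinates[0], label="first_frame")
    cov = covariance_matrix(ens)
    spec = qh_modes(cov, topology, config.temperature,
                    drop_tol=config.mode_drop_tol)
    total = config_entropy(spec)
    resids = np.unique(topology.residue_index)
    per_res = np.array([
        residue_entropy(cov, topology, int(r), config.temperature).S
        for r in resids])
    return total, per_res, spec, ens.n_frames


def run_pipeline(config: RunConfig, topology: Topology,
                 runs: dict[tuple[str, int], FrameEnsemble]) -> dict:
    """Run the whole chain over a scan and write the output bundle.

    ``runs`` maps (state, rigid_residue) — rigid_residue 0 for unperturbed —
    to frame ensembles. Writes entropy ledger CSVs, ΔS/ΔΔS tables, spectra
    and PCA contributions under ``config.output_dir``; returns artifact paths.
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    ledger = EntropyLedger()
    pca_rows = []
    for (state, rigid), ens in sorted(runs.items()):
        total, per_res, spec, n_frames = analyze_run(ens, topology, config)
        ledger.add_run(state, rigid, total.S, n_frames, per_res)
        save_spectrum(spec, os.path.join(out, f"spectrum_{state}_rigid{rigid:03d}.h5"))
        fractions, cumulative, n90 = pca_contributions(spec)
        pca_rows.append({"state": state, "rigid_residue": rigid,
                         "n_modes_90pct": n90,
                         "pc1_fraction": float(fractions[0])})
    paths = {}
    paths["ledger"] = os.path.join(out, "entropy_ledger.csv")
    ledger.to_csv(paths["ledger"])
    paths["pca"] = os.path.join(out, "pca_contributions.csv")
    pd.DataFrame(pca_rows).to_csv(paths["pca"], index=False)
    states = ledger.states()
    for state in states:
        p = os.path.join(out, f"delta_entropy_{state}.csv")
        delta_entropy(ledger, state).to_csv(p, index=False)
        paths[f"delta_{state}"] = p
    if {"unbound", "bound"} <= set(states):
        p = os.path.join(out, "delta_delta_entropy.csv")
        delta_delta_entropy(ledger).to_csv(p, index=False)
        paths["delta_delta"] = p
    meta = {"config": config.to_dict(), "config_hash": config.digest,
            "seed": config.seed, "version": __version__,
            "runs": [f"{s}:{r}" for s, r in sorted(runs)]}
    paths["metadata"] = os.path.join(out, "metadata.json")
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return paths
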