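"""Scan-level bookkeeping: ΔS, ΔΔS, key-residue screen, response maps, CIs.

A rigid-residue scan produces one run per (state, rigid residue) pair, with
rigid_residue = 0 denoting the unperturbed run of that state. All the
quantities here are exact linear bookkeeping over the per-run entropies, plus
a Student-t confidence interval for repeated-trajectory error bars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Convention: rigid_residue == 0 is the unperturbed run.
UNPERTURBED = 0


@dataclass
class EntropyLedger:
    """Per-run total entropies and per-residue entropy vectors.

    ``runs`` has one row per (state, rigid_residue) with columns
    state, rigid_residue, S, n_frames; ``per_residue[(state, rr)]`` holds the
    length-R vector of residue entropy contributions for that run.
    """

    runs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["state", "rigid_residue", "S", "n_frames"]))
    per_residue: dict = field(default_factory=dict)

    def add_run(self, state: str, rigid_residue: int, S: float, n_frames: int,
                residue_entropies: np.ndarray | None = None) -> None:
        key = (state, int(rigid_residue))
        if ((self.runs["state"] == state) &
                (self.runs["rigid_residue"] == int(rigid_residue))).any():
            raise ValueError(f"duplicate ledger row for {key}")
        self.runs.loc[len(self.runs)] = [state, int(rigid_residue), float(S), int(n_frames)]
        if residue_entropies is not None:
            self.per_residue[key] = np.asarray(residue_entropies, dtype=float)

    def entropy(self, state: str, rigid_residue: int = UNPERTURBED) -> float:
        sel = self.runs[(self.runs["state"] == state) &
                        (self.runs["rigid_residue"] == rigid_residue)]
        if sel.empty:
            raise KeyError(f"no ledger row for ({state}, rigid={rigid_residue})")
        return float(sel["S"].iloc[0])

    def states(self) -> list[str]:
        return sorted(self.runs["state"].unique())

    def to_csv(self, path: str) -> None:
        self.runs.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "EntropyLedger":
        return cls(runs=pd.read_csv(path))


def delta_entropy(ledger: EntropyLedger, state: str,
                  reference_state: str | None = None) -> pd.DataFrame:
    """ΔS(run) = S(run) − S(reference unperturbed run) for one state.

    By default each state is referenced to its own unperturbed run; pass
    ``reference_state`` to reference everything to (say) the unbound
    unperturbed run instead.
    """
    ref_state = reference_state if reference_state is not None else state
    ref = ledger.entropy(ref_state, UNPERTURBED)
    rows = ledger.runs[ledger.runs["state"] == state].sort_values("rigid_residue")
    return pd.DataFrame({
        "rigid_residue": rows["rigid_residue"].to_numpy(),
        "delta_S": rows["S"].to_numpy() - ref,
    })


def delta_delta_entropy(ledger: EntropyLedger, bound_state: str = "bound",
                        unbound_state: str = "unbound") -> pd.DataFrame:
    """ΔΔS(r) = S_bound(r) − S_unbound(r) for every matched rigid residue.

    Includes r = 0 (the unperturbed pair). Residues present in only one state
    are skipped with a warning.
    """
    b = ledger.runs[ledger.runs["state"] == bound_state].set_index("rigid_residue")["S"]
    u = ledger.runs[ledger.runs["state"] == unbound_state].set_index("rigid_residue")["S"]
    common = sorted(set(b.index) & set(u.index))
    missing = sorted(set(b.index) ^ set(u.index))
    if missing:
        warnings.warn(f"rigid residues present in one state only, skipped: {missing}")
    return pd.DataFrame({
        "rigid_residue": common,
        "delta_delta_S": [b[r] - u[r] for r in common],
    })


def key_residue_screen(dds: pd.DataFrame, reference_dds: float) -> pd.DataFrame:
    """Residues whose |ΔΔS| falls strictly below the unperturbed-pair |ΔΔS|.

    A rigid residue that shrinks the bound/unbound entropy gap below its
    unperturbed value is flagged as a candidate allosteric residue. Returned
    sorted ascending by |ΔΔS|; the unperturbed row itself is excluded.
    """
    rows = dds[dds["rigid_residue"] != UNPERTURBED].copy()
    rows["abs_dds"] = rows["delta_delta_S"].abs()
    hits = rows[rows["abs_dds"] < reference_dds].sort_values(
        ["abs_dds", "rigid_residue"]).reset_index(drop=True)
    return hits[["rigid_residue", "delta_delta_S", "abs_dds"]]


def residue_response_map(ledger: EntropyLedger, state: str) -> pd.DataFrame:
    """Per-residue entropy responses, rigid-run × residue.

    Element (run r, residue j) = S_j(run r) − S_j(unperturbed), so the
    unperturbed row is identically zero and the self-rigid diagonal is
    expected strongly negative (the residue's internal freedom is gone).
    Rows indexed by rigid_residue (0 first), columns by residue id.
    """
    ref_key = (state, UNPERTURBED)
    if ref_key not in ledger.per_residue:
        raise KeyError(f"missing unperturbed per-residue vector for state {state!r}")
    ref = ledger.per_residue[ref_key]
    keys = sorted((k for k in ledger.per_residue if k[0] == state), key=lambda k: k[1])
    data = {k[1]: ledger.per_residue[k] - ref for k in keys}
    df = pd.DataFrame.from_dict(data, orient="index",
                                columns=np.arange(1, ref.size + 1))
    df.index.name = "rigid_residue"
    return df


def average_response(response_map: pd.DataFrame,
                     include_diagonal: bool = True) -> pd.Series:
    """Mean entropic response per residue over all rigid runs.

    The unperturbed (rigid_residue = 0) row is excluded. With
    ``include_diagonal=False`` the self-rigid cell of each run (residue j in
    the run where j itself is rigid) is masked out of residue j's mean.
    """
    rigid = response_map[response_map.index != UNPERTURBED]
    if rigid.empty:
        raise ValueError("response map holds no rigid runs")
    if include_diagonal:
        return rigid.mean(axis=0)
    masked = rigid.copy().astype(float)
    for r in masked.index:
        if r in masked.columns:
            masked.loc[r, r] = np.nan
    return masked.mean(axis=0, skipna=True)


@dataclass(frozen=True)
class MeanCI:
    mean: float
    sd: float
    half_width: float
    n: int
    level: float


def ci_half_width(sd: float, n: int, level: float = 0.85) -> float:
    """Student-t half-width t_{1−α/2, n−1}·sd/√n for a repeated-run mean."""
    if n < 2:
        raise ValueError("need at least 2 samples")
    t = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return float(t * sd / np.sqrt(n))


def mean_ci(samples, level: float = 0.85) -> MeanCI:
    """Sample mean, SD (n−1 divisor) and two-sided Student-t CI half-width."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    sd = float(x.std(ddof=1))
    return MeanCI(mean=float(x.mean()), sd=sd,
                  half_width=ci_half_width(sd, x.size, level),
                  n=int(x.size), level=level)
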