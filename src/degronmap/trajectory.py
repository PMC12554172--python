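"""Post-processing of multi-trial MD trajectories of docked poses.

Trajectories of a two-chain complex (chain A = receptor, chain B = bound
peptide), coarse-grained to one Cα per residue, are analysed for binding
stability: per-frame RMSD against the production-start conformation after
least-squares superposition, trial-aggregated mean/variance series,
burn-in removal, trial-averaged Cα contact-frequency maps (0-1 normalized,
0.8 nm cutoff) and a composite pose-stability ranking.

All trajectory math is in nanometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RECEPTOR_CHAIN = "A"
PEPTIDE_CHAIN = "B"


class DegenerateGeometryError(ValueError):
    """Point cloud is collinear or otherwise too degenerate to superpose."""


class BurnInError(ValueError):
    """Burn-in discard leaves no analysable frames."""


@dataclass
class TrajectoryEnsemble:
    """Cα coordinates for poses x trials x frames of a two-chain complex.

    ``coords`` maps ``(pose, trial)`` to an array of shape
    ``(n_frames, n_residues, 3)`` in nm; ``chains`` and ``resids`` give the
    chain id and residue number of each coordinate column, shared by all
    trajectories of the ensemble.
    """

    coords: dict[tuple[int, int], np.ndarray]
    chains: np.ndarray
    resids: np.ndarray
    frame_spacing_ps: float = 10.0

    def __post_init__(self) -> None:
        self.chains = np.asarray(self.chains)
        self.resids = np.asarray(self.resids)
        n_atoms = len(self.resids)
        if len(self.chains) != n_atoms:
            raise ValueError("chains and resids length mismatch")
        for chain in np.unique(self.chains):
            r = self.resids[self.chains == chain]
            if len(np.unique(r)) != len(r):
                raise ValueError(f"duplicate residue numbers in chain {chain}")
        for key, arr in self.coords.items():
            if arr.ndim != 3 or arr.shape[1] != n_atoms or arr.shape[2] != 3:
                raise ValueError(f"trajectory {key} has shape {arr.shape}, expected (*, {n_atoms}, 3)")

    @property
    def poses(self) -> list[int]:
        return sorted({p for p, _ in self.coords})

    def trials(self, pose: int) -> list[int]:
        return sorted({t for p, t in self.coords if p == pose})

    def selection_mask(self, selection: str) -> np.ndarray:
        if selection == "peptide":
            return self.chains == PEPTIDE_CHAIN
        if selection == "receptor":
            return self.chains == RECEPTOR_CHAIN
        if selection == "complex":
            return np.ones(len(self.chains), dtype=bool)
        raise ValueError(f"unknown selection {selection!r}")


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition of two paired point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to
    ``reference``; the rotation is proper (determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point counts differ: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    x = mobile - mob_c
    y = reference - ref_c
    scale = max(np.abs(x).max(), np.abs(y).max(), 1.0)
    if (
        np.linalg.matrix_rank(x, tol=1e-10 * scale) < 2
        or np.linalg.matrix_rank(y, tol=1e-10 * scale) < 2
    ):
        raise DegenerateGeometryError("all points collinear; rotation is underdetermined")
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ref_c - rotation @ mob_c
    moved = x @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return rotation, translation, rmsd


@dataclass
class RMSDSeries:
    """Per-frame RMSD (nm) of a selection against the trial's first frame."""

    values: np.ndarray
    selection: str
    pose: int
    trial: int
    frame_spacing_ps: float = 10.0

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_spacing_ps


def rmsd_series(
    ensemble: TrajectoryEnsemble, pose: int, trial: int, selection: str = "peptide"
) -> RMSDSeries:
    """RMSD of a selection versus the production-start conformation.

    The reference is frame 0 of the same trial; every frame is superposed
    on the selection's own Cα atoms by least squares before the deviation
    is measured, so rigid-body motion of the selection does not register.
    """
    mask = ensemble.selection_mask(selection)
    traj = ensemble.coords[(pose, trial)]
    ref = traj[0][mask]
    values = np.empty(traj.shape[0])
    for i, frame in enumerate(traj):
        _, _, values[i] = kabsch_superpose(frame[mask], ref)
    return RMSDSeries(values, selection, pose, trial, ensemble.frame_spacing_ps)


@dataclass
class RMSDAggregate:
    """Pointwise mean and variance of RMSD series across trials."""

    mean: np.ndarray
    variance: np.ndarray
    n_trials: int
    selection: str
    pose: int


def aggregate_rmsd(series: Sequence[RMSDSeries]) -> RMSDAggregate:
    """Pointwise mean and (population) variance across simulation trials."""
    if not series:
        raise ValueError("no trials to aggregate")
    lengths = {len(s.values) for s in series}
    n = min(lengths)
    if len(lengths) > 1:
        warnings.warn(
            f"series lengths differ ({sorted(lengths)}); truncating to {n}",
            UserWarning,
            stacklevel=2,
        )
    if len(series) == 1:
        warnings.warn("single trial: variance is identically zero", UserWarning, stacklevel=2)
    stacked = np.stack([s.values[:n] for s in series])
    return RMSDAggregate(
        mean=stacked.mean(axis=0),
        variance=stacked.var(axis=0),
        n_trials=len(series),
        selection=series[0].selection,
        pose=series[0].pose,
    )


@dataclass(frozen=True)
class ContactParams:
    """Contact-analysis parameters.

    ``cutoff_nm``: Cα-Cα contact cutoff; two residues are in contact when
    their Cα distance is strictly below it (d == cutoff is no contact).
    ``burn_in``: frames discarded from the start of every trial.
    ``stride``: keep every ``stride``-th retained frame.
    """

    cutoff_nm: float = 0.8
    burn_in: int = 500
    stride: int = 1

    def __post_init__(self) -> None:
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class ContactMap:
    """Receptor-residue x peptide-residue contact frequencies in [0, 1].

    ``freq`` rows are receptor residue numbers, columns peptide residue
    numbers.  A value of 1 means the pair was within the cutoff in every
    retained frame of every trial; 0 means it never was.
    """

    freq: pd.DataFrame
    params: ContactParams
    pose: int
    n_trials: int

    def max_entry(self) -> float:
        return float(self.freq.to_numpy().max()) if self.freq.size else 0.0


def contact_frequency(
    ensemble: TrajectoryEnsemble, pose: int, params: ContactParams | None = None
) -> ContactMap:
    """Trial-averaged Cα contact-frequency map for one pose.

    Within each trial the indicator of Cα distance < cutoff is averaged
    over retained (post burn-in, strided) frames; the per-trial frequencies
    are then averaged over trials.  With equal frame counts this equals
    pooling all frames.
    """
    params = params or ContactParams()
    rec = ensemble.selection_mask("receptor")
    pep = ensemble.selection_mask("peptide")
    if not rec.any() or not pep.any():
        raise ValueError("ensemble must contain both receptor and peptide chains")
    trials = ensemble.trials(pose)
    if not trials:
        raise KeyError(f"no trials for pose {pose}")
    per_trial = []
    for trial in trials:
        traj = ensemble.coords[(pose, trial)]
        retained = traj[params.burn_in :: params.stride]
        if retained.shape[0] == 0:
            raise BurnInError(
                f"burn-in {params.burn_in} >= trial length {traj.shape[0]} "
                f"(pose {pose}, trial {trial})"
            )
        diff = retained[:, rec, None, :] - retained[:, None, pep, :]
        dist = np.sqrt(np.sum(diff**2, axis=-1))
        per_trial.append((dist < params.cutoff_nm).mean(axis=0))
    freq = np.mean(per_trial, axis=0)
    frame = pd.DataFrame(freq, index=ensemble.resids[rec], columns=ensemble.resids[pep])
    frame.index.name = "receptor_residue"
    frame.columns.name = "peptide_residue"
    return ContactMap(freq=frame, params=params, pose=pose, n_trials=len(trials))


def rank_pose_stability(
    aggregates: Mapping[int, RMSDAggregate],
    maps: Mapping[int, ContactMap] | None = None,
) -> pd.DataFrame:
    """Rank poses by binding stability.

    The composite score per pose is the pair (time-mean peptide RMSD,
    time-mean trial variance), ranked ascending lexicographically — smallest
    drift first, then lowest variance.  Exact ties are broken by the maximum
    contact-map entry (descending: more persistent contacts rank higher) and
    finally by pose label.

    Returns a frame sorted by rank with columns
    ``pose, drift_nm, rmsd_variance_nm2, max_contact, rank``.
    """
    if not aggregates:
        raise ValueError("no poses to rank")
    rows = []
    for pose, agg in aggregates.items():
        rows.append(
            {
                "pose": pose,
                "drift_nm": float(agg.mean.mean()),
                "rmsd_variance_nm2": float(agg.variance.mean()),
                "max_contact": maps[pose].max_entry() if maps and pose in maps else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    tie_break = -out["max_contact"].fillna(0.0)
    out = (
        out.assign(_tb=tie_break)
        .sort_values(["drift_nm", "rmsd_variance_nm2", "_tb", "pose"])
        .drop(columns="_tb")
        .reset_index(drop=True)
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
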