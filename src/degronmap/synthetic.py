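"""Synthetic generators for every input the analysis modules consume.

The wet-lab and simulation inputs of a degron-mapping study — replicated
substitution-array fluorescence, multi-trial two-chain Cα trajectories,
two-channel SPR isotherms and cycloheximide-chase decay courses — are
emulated here with known ground truth, so the whole pipeline is testable
without any instrument output.  All generators are deterministic given a
seed, and with the noise model switched off every observable equals its
closed-form expectation exactly.

The trajectory generator is a *kinematic* construction (synthetic
geometry): residues are placed so that prescribed Cα contact occupancies
and drift/variance profiles are realized exactly; no force field is
involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arrays import (
    AMINO_ACIDS,
    RGS2_DEGRON,
    ArrayDesign,
    SubstitutionArrayDataset,
    UnknownResidueError,
    check_parent_sequence,
    enumerate_peptides,
)
from .binding import BindingIsotherm, twofold_series
from .trajectory import PEPTIDE_CHAIN, RECEPTOR_CHAIN, TrajectoryEnsemble
from .turnover import DecayCourse

NOISE_MODELS = ("none", "lognormal", "gaussian")

# substream ids: one global seed fans out to independent per-generator streams
_STREAM_ARRAY = 1
_STREAM_TRAJ = 2
_STREAM_ISOTHERM = 3
_STREAM_CHASE = 4
_STREAM_STABILITY = 5


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared randomness/noise settings for all generators.

    ``noise_model``: ``none`` for exact expectations, ``lognormal`` for
    multiplicative noise (fluorescence, densitometry — positive, skewed;
    ``noise_scale`` is the log-sd, ~CV for small values), ``gaussian`` for
    additive noise (SPR responses; scale is in response units relative to
    the signal amplitude, trajectory jitter in nm).
    """

    seed: int = 0
    noise_model: str = "none"
    noise_scale: float = 0.0
    n_replicates: int = 9

    def __post_init__(self) -> None:
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}; use one of {NOISE_MODELS}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(stream), int(self.seed)])


@dataclass(frozen=True)
class EffectProfile:
    """Ground-truth multiplicative effects of substitutions and truncations.

    ``effect[(position, residue)]`` multiplies the parent signal for the
    peptide carrying that substitution; the parent residue at each position
    has factor 1 exactly.  ``truncation_effect[last_retained]`` does the
    same for C-terminal truncation peptides.
    """

    parent_sequence: str
    effect: Mapping[tuple[int, str], float]
    truncation_effect: Mapping[int, float]
    position_offset: int = 5

    def __post_init__(self) -> None:
        check_parent_sequence(self.parent_sequence)
        positions = range(
            self.position_offset, self.position_offset + len(self.parent_sequence)
        )
        for (pos, aa), f in self.effect.items():
            if aa not in AMINO_ACIDS:
                raise UnknownResidueError(f"unknown residue letter {aa!r} in profile")
            if pos not in positions:
                raise ValueError(f"profile position {pos} outside parent range")
            if not (np.isfinite(f) and f >= 0):
                raise ValueError(f"effect factor at ({pos}, {aa}) must be finite and >= 0")
        for pos in positions:
            parent_aa = self.parent_sequence[pos - self.position_offset]
            if self.effect.get((pos, parent_aa), 1.0) != 1.0:
                raise ValueError(f"parent-residue effect at position {pos} must be exactly 1")
        for last, f in self.truncation_effect.items():
            if not (np.isfinite(f) and f >= 0):
                raise ValueError(f"truncation factor at {last} must be finite and >= 0")

    def factor(self, position: int, residue: str) -> float:
        parent_aa = self.parent_sequence[position - self.position_offset]
        if residue == parent_aa:
            return 1.0
        return float(self.effect.get((position, residue), 1.0))

    @classmethod
    def flat(cls, parent_sequence: str = RGS2_DEGRON, position_offset: int = 5) -> "EffectProfile":
        """Null profile: every substitution and truncation leaves the signal unchanged."""
        n = len(parent_sequence)
        trunc = {position_offset + i: 1.0 for i in range(n)}
        return cls(parent_sequence, {}, trunc, position_offset)


def rgs2_degron_profile() -> EffectProfile:
    """Ground-truth profile encoding the RGS2 degron substitution pattern.

    Positions 5-10 (the hydrophobic N-terminal half) are inert; Cys13 is
    essential (every substitution but Arg/Lys collapses binding, bulky
    aromatics retain partial signal); substitutions at Asp12 improve
    binding across the board; Arg (and mostly Lys) substitutions in the
    11-16 half enhance binding, consistent with a negatively charged
    receptor interface; Pro15 -> Ala/Gly weakens binding.  Truncations keep
    near-full signal down to a last-retained position of 13 and lose
    essentially all binding once Cys13 is removed.
    """
    seq = RGS2_DEGRON  # positions 5..16
    effect: dict[tuple[int, str], float] = {}

    def set_all(pos: int, value: float, **overrides: float) -> None:
        parent_aa = seq[pos - 5]
        for aa in AMINO_ACIDS:
            if aa == parent_aa:
                continue
            effect[(pos, aa)] = overrides.get(aa, value)

    # positions 5-10: inert (factor 1 everywhere) — nothing to set
    set_all(11, 1.0, R=1.5, K=1.2)
    set_all(12, 1.5, R=2.5, K=2.0)
    set_all(13, 0.02, R=1.3, K=0.9, W=0.6, Y=0.6)
    set_all(14, 1.0, A=0.6, W=0.6)
    set_all(15, 1.0, A=0.7, G=0.7, R=1.6, K=1.3)
    set_all(16, 1.0, R=1.5, K=1.2)
    truncation_effect = {16: 1.0, 15: 0.95, 14: 0.9, 13: 0.9}
    truncation_effect.update({last: 0.02 for last in range(5, 13)})
    return EffectProfile(seq, effect, truncation_effect)


def gen_array_signals(
    profile: EffectProfile,
    parent_signal: float = 1000.0,
    config: GeneratorConfig = GeneratorConfig(),
) -> SubstitutionArrayDataset:
    """Generate a replicated substitution/truncation array dataset.

    Every peptide's expected signal is ``parent_signal`` times its profile
    factor; replicates are drawn per the config noise model (lognormal
    multiplies by exp(N(0, scale)); gaussian adds N(0, scale *
    parent_signal), clipped at 0).
    """
    if parent_signal <= 0:
        raise ValueError("parent_signal must be positive")
    design = ArrayDesign(
        parent_sequence=profile.parent_sequence,
        position_offset=profile.position_offset,
        truncations=tuple(sorted(profile.truncation_effect, reverse=True)),
    )
    peptides = enumerate_peptides(design)
    rng = config.rng(_STREAM_ARRAY)
    rows = []
    for pep in peptides.itertuples(index=False):
        if pep.kind == "truncation":
            expected = parent_signal * float(profile.truncation_effect[pep.trunc_last])
        else:
            expected = parent_signal * profile.factor(pep.position, pep.residue)
        for rep in range(config.n_replicates):
            val = expected
            if config.noise_model == "lognormal":
                val *= math.exp(rng.normal(0.0, config.noise_scale))
            elif config.noise_model == "gaussian":
                val = max(0.0, val + rng.normal(0.0, config.noise_scale * parent_signal))
            rows.append(
                {
                    "peptide_id": pep.peptide_id,
                    "kind": pep.kind,
                    "position": pep.position,
                    "residue": pep.residue,
                    "trunc_last": pep.trunc_last,
                    "replicate": rep,
                    "signal": val,
                }
            )
    return SubstitutionArrayDataset(design=design, signals=pd.DataFrame(rows))


_CONTACT_NM = 0.5  # Cα distance realized during a contact frame
_APART_NM = 1.5  # distance during a no-contact frame
_SITE_SPACING_NM = 10.0  # spacing between receptor sites; keeps unlisted pairs far apart


def gen_trajectories(
    occupancy: Mapping[tuple[int, int], float],
    n_trials: int = 4,
    n_frames: int = 200,
    n_poses: int = 1,
    config: GeneratorConfig = GeneratorConfig(),
    frame_spacing_ps: float = 10.0,
) -> TrajectoryEnsemble:
    """Generate two-chain Cα trajectories with prescribed contact occupancies.

    ``occupancy`` maps (receptor residue, peptide residue) pairs to the
    target fraction of frames with Cα distance below 0.8 nm.  Each peptide
    residue may be paired with one receptor residue; receptor sites are
    placed 10 nm apart so unlisted cross-chain pairs always stay far beyond
    the cutoff, and a paired peptide residue sits at 0.5 nm (contact
    frames) or 1.5 nm (apart frames) from its site.  The number of contact
    frames per trial is ``round(f * n_frames)``, scheduled first-frames-
    first when noise is off and by random permutation otherwise; Gaussian
    coordinate jitter of ``noise_scale`` nm is added under either noise
    model (small jitter cannot flip the contact state given the 0.3 nm
    margins).
    """
    if n_frames < 1 or n_trials < 1 or n_poses < 1:
        raise ValueError("n_frames, n_trials and n_poses must be >= 1")
    if not occupancy:
        raise ValueError("occupancy map must not be empty")
    for pair, f in occupancy.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"occupancy for pair {pair} must be in [0, 1], got {f}")
    pep_partners: dict[int, int] = {}
    for ri, rj in occupancy:
        if rj in pep_partners and pep_partners[rj] != ri:
            raise ValueError(
                f"peptide residue {rj} is paired with multiple receptor residues; "
                "one partner per peptide residue"
            )
        pep_partners[rj] = ri

    rec_resids = sorted({ri for ri, _ in occupancy})
    pep_resids = sorted({rj for _, rj in occupancy})
    # sites on a wide helix: mutually far apart (> 4 nm) yet never collinear,
    # so peptide selections stay superposable
    rec_pos = {
        ri: _SITE_SPACING_NM * np.array([math.cos(k), math.sin(k), 0.5 * k])
        for k, ri in enumerate(rec_resids)
    }
    chains = np.array([RECEPTOR_CHAIN] * len(rec_resids) + [PEPTIDE_CHAIN] * len(pep_resids))
    resids = np.array(rec_resids + pep_resids)

    rng = config.rng(_STREAM_TRAJ)
    coords: dict[tuple[int, int], np.ndarray] = {}
    for pose in range(1, n_poses + 1):
        for trial in range(n_trials):
            traj = np.zeros((n_frames, len(resids), 3))
            for k, ri in enumerate(rec_resids):
                traj[:, k, :] = rec_pos[ri]
            for k, rj in enumerate(pep_resids):
                ri = pep_partners[rj]
                f = occupancy[(ri, rj)]
                n_contact = int(round(f * n_frames))
                in_contact = np.zeros(n_frames, dtype=bool)
                if config.noise_model == "none":
                    in_contact[:n_contact] = True
                else:
                    idx = rng.permutation(n_frames)[:n_contact]
                    in_contact[idx] = True
                d = np.where(in_contact, _CONTACT_NM, _APART_NM)
                col = len(rec_resids) + k
                traj[:, col, 0] = rec_pos[ri][0] + d
                traj[:, col, 1] = rec_pos[ri][1]
                traj[:, col, 2] = rec_pos[ri][2]
            if config.noise_model != "none" and config.noise_scale > 0:
                traj += rng.normal(0.0, config.noise_scale, size=traj.shape)
            coords[(pose, trial)] = traj
    return TrajectoryEnsemble(
        coords=coords, chains=chains, resids=resids, frame_spacing_ps=frame_spacing_ps
    )


def _helix(n: int, radius: float, rise: float, origin: np.ndarray) -> np.ndarray:
    theta = np.arange(n) * 100.0 * np.pi / 180.0
    return origin + np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * np.arange(n)], axis=1
    )


def gen_stability_ensemble(
    drift_nm: Sequence[float] = (0.10, 0.40, 0.50, 0.60, 0.12),
    trial_spread: Sequence[float] = (0.10, 0.35, 0.35, 0.35, 0.10),
    n_trials: int = 4,
    n_frames: int = 200,
    n_peptide_res: int = 22,
    n_receptor_res: int = 30,
    config: GeneratorConfig = GeneratorConfig(),
    frame_spacing_ps: float = 10.0,
) -> TrajectoryEnsemble:
    """Generate an ensemble of poses with planted drift/variance ordering.

    Emulates a set of predicted binding poses re-simulated in several
    independent trials, two of which (poses 1 and 5 by default) are stable
    — small drift from the starting conformation and low trial-to-trial
    variance — while the rest unbind progressively.  Peptide "drift" is
    realized as a gradual internal deformation (isotropic expansion about
    the centroid) whose amplitude ramps linearly to ``drift_nm[pose-1] *
    g_trial`` over the trajectory, with ``g_trial = exp(N(0,
    trial_spread[pose-1]))`` a per-trial lognormal factor; the peptide-
    selection RMSD versus frame 0 therefore ramps to exactly that amplitude
    (superposition cannot absorb a pure scaling).  The receptor stays
    rigid.
    """
    if len(drift_nm) != len(trial_spread):
        raise ValueError("drift_nm and trial_spread must have equal length")
    rng = config.rng(_STREAM_STABILITY)
    rec0 = _helix(n_receptor_res, radius=0.4, rise=0.15, origin=np.zeros(3))
    pep0 = _helix(n_peptide_res, radius=0.3, rise=0.15, origin=np.array([1.2, 0.0, 0.0]))
    pep_centroid = pep0.mean(axis=0)
    pep_centered = pep0 - pep_centroid
    r_gyr = float(np.sqrt(np.mean(np.sum(pep_centered**2, axis=1))))
    chains = np.array([RECEPTOR_CHAIN] * n_receptor_res + [PEPTIDE_CHAIN] * n_peptide_res)
    resids = np.concatenate([np.arange(1, n_receptor_res + 1), np.arange(1, n_peptide_res + 1)])
    ramp = np.arange(n_frames) / max(n_frames - 1, 1)
    coords: dict[tuple[int, int], np.ndarray] = {}
    for pose, (amp, spread) in enumerate(zip(drift_nm, trial_spread), start=1):
        for trial in range(n_trials):
            g = math.exp(rng.normal(0.0, spread)) if spread > 0 else 1.0
            lam = amp * g * ramp / r_gyr
            traj = np.empty((n_frames, len(resids), 3))
            traj[:, :n_receptor_res, :] = rec0
            traj[:, n_receptor_res:, :] = (
                pep_centroid + (1.0 + lam)[:, None, None] * pep_centered
            )
            coords[(pose, trial)] = traj
    return TrajectoryEnsemble(
        coords=coords, chains=chains, resids=resids, frame_spacing_ps=frame_spacing_ps
    )


def gen_isotherm(
    kd: float,
    bmax: float,
    conc_series: Sequence[float] | None = None,
    nonspecific_slope: float = 1.0,
    config: GeneratorConfig = GeneratorConfig(),
) -> BindingIsotherm:
    """Generate a two-channel equilibrium SPR isotherm.

    Reference channel (Fc1, blank surface): ``nonspecific_slope * C``.
    Measurement channel (Fc2): one-site Langmuir specific binding
    ``bmax * C / (kd + C)`` plus the same nonspecific term.  The default
    concentration series is the 9-point two-fold dilution from 0.29 to
    75 μM.  Lognormal noise multiplies each channel value by
    ``exp(N(0, scale))``; gaussian noise adds ``N(0, scale * bmax)``.
    """
    if kd <= 0 or bmax <= 0:
        raise ValueError("kd and bmax must be positive")
    conc = np.asarray(conc_series if conc_series is not None else twofold_series(), dtype=float)
    if (conc <= 0).any():
        raise ValueError("all concentrations must be positive")
    conc = np.sort(conc)
    rng = config.rng(_STREAM_ISOTHERM)
    fc1 = nonspecific_slope * conc
    fc2 = bmax * conc / (kd + conc) + nonspecific_slope * conc
    if config.noise_model == "lognormal":
        fc1 = fc1 * np.exp(rng.normal(0.0, config.noise_scale, size=conc.shape))
        fc2 = fc2 * np.exp(rng.normal(0.0, config.noise_scale, size=conc.shape))
    elif config.noise_model == "gaussian":
        fc1 = fc1 + rng.normal(0.0, config.noise_scale * bmax, size=conc.shape)
        fc2 = fc2 + rng.normal(0.0, config.noise_scale * bmax, size=conc.shape)
    return BindingIsotherm(
        pd.DataFrame({"concentration_uM": conc, "ru_fc1": fc1, "ru_fc2": fc2})
    )


def gen_chase(
    t_half: float,
    timepoints: Sequence[float] = (0, 10, 20, 30, 45, 60),
    config: GeneratorConfig = GeneratorConfig(),
    condition: str = "",
) -> DecayCourse:
    """Generate a cycloheximide-chase decay course.

    Expected abundance follows ``100% * 2^(-t / t_half)``.  Noise is applied
    to the raw band intensities and each replicate is then renormalized to
    its own t=0 value, exactly as chase densitometry is processed — so t=0
    is 100% by construction even under noise.
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    timepoints = np.asarray(timepoints, dtype=float)
    if 0.0 not in timepoints:
        raise ValueError("timepoints must include 0")
    rng = config.rng(_STREAM_CHASE)
    rows = []
    for rep in range(config.n_replicates):
        raw = np.power(2.0, -timepoints / t_half)
        if config.noise_model == "lognormal":
            raw = raw * np.exp(rng.normal(0.0, config.noise_scale, size=raw.shape))
        elif config.noise_model == "gaussian":
            raw = np.maximum(raw + rng.normal(0.0, config.noise_scale, size=raw.shape), 1e-12)
        t0 = raw[timepoints == 0.0][0]
        pct = 100.0 * raw / t0
        for t, v in zip(timepoints, pct):
            rows.append({"timepoint_min": t, "replicate": rep, "abundance_pct": v})
    return DecayCourse(pd.DataFrame(rows), condition=condition)
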