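"""Substitution/truncation peptide-array analysis.

A positional substitution scan prints, for every position of a parent
peptide, one peptide per alternative amino acid, plus a series of
C-terminal truncations.  Bound-probe fluorescence per peptide, replicated,
is the raw input.  This module normalizes signals to the parent residue at
each position, calls significant substitution effects (two-way ANOVA with
Tukey contrasts against the parent within each position), classifies
positions (essential / charge-enhanced / mixed / tolerant) and locates the
truncation boundary past which binding is lost.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical RGS2 degron peptide, residues 5-16.
RGS2_DEGRON: str = "MFLAVQHDCRPM"
#: Alternate spelling that circulates with Cys/Arg swapped; accepted with a warning.
RGS2_DEGRON_SWAPPED: str = "MFLAVQHDRCPM"


class UnknownResidueError(ValueError):
    """A residue letter outside the 20 natural amino acids was supplied."""


class ParentSignalError(ValueError):
    """Parent-residue reference signal at a position is at or below the floor."""


def check_parent_sequence(sequence: str, alphabet: str = AMINO_ACIDS) -> str:
    """Validate a parent peptide sequence.

    The RGS2 degron is printed in the literature with two spellings that
    differ by a Cys/Arg swap; the swapped variant is accepted but flagged,
    since residue-role assignments (Asp12, Cys13, Arg14) only match the
    canonical spelling.
    """
    bad = sorted(set(sequence) - set(alphabet))
    if bad:
        raise UnknownResidueError(f"unknown residue letter(s): {bad}")
    if sequence == RGS2_DEGRON_SWAPPED:
        warnings.warn(
            "parent sequence matches the Cys/Arg-swapped spelling of the RGS2 "
            f"degron ({RGS2_DEGRON_SWAPPED}); the canonical spelling is "
            f"{RGS2_DEGRON}",
            UserWarning,
            stacklevel=2,
        )
    return sequence


@dataclass(frozen=True)
class ArrayDesign:
    """Layout of a positional substitution/truncation array.

    Parameters
    ----------
    parent_sequence
        Parent peptide, one letter per position.
    position_offset
        Residue number of the first parent position (5 for RGS2 5-16).
    truncations
        Last-retained parent positions of the C-terminal truncation series,
        strictly decreasing from the full-length peptide.
    alphabet
        Substitution alphabet; the 20 natural amino acids.
    """

    parent_sequence: str
    position_offset: int = 5
    truncations: tuple[int, ...] = ()
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        check_parent_sequence(self.parent_sequence, AMINO_ACIDS)
        bad = sorted(set(self.alphabet) - set(AMINO_ACIDS))
        if bad:
            raise UnknownResidueError(f"alphabet letter(s) outside the 20 natural amino acids: {bad}")
        if self.truncations:
            t = list(self.truncations)
            if any(b >= a for a, b in zip(t, t[1:])):
                raise ValueError("truncations must be strictly decreasing")
            if t[0] > self.positions[-1] or t[-1] < self.position_offset:
                raise ValueError("truncations fall outside the parent position range")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(range(self.position_offset, self.position_offset + len(self.parent_sequence)))

    def parent_residue(self, position: int) -> str:
        return self.parent_sequence[position - self.position_offset]

    def truncated_sequence(self, last_retained: int) -> str:
        return self.parent_sequence[: last_retained - self.position_offset + 1]


def enumerate_peptides(design: ArrayDesign) -> pd.DataFrame:
    """List every peptide printed on the array.

    One peptide per (position, non-parent residue), one parent-residue
    reference peptide per position (the parent sequence repeated as the
    in-cell reference), and one peptide per C-terminal truncation.

    Returns a frame with columns ``peptide_id, kind, position, residue,
    trunc_last, sequence``; ``kind`` is one of ``substitution``, ``parent``,
    ``truncation``.
    """
    rows = []
    seq = design.parent_sequence
    off = design.position_offset
    for pos in design.positions:
        parent_aa = design.parent_residue(pos)
        for aa in design.alphabet:
            kind = "parent" if aa == parent_aa else "substitution"
            mutated = seq[: pos - off] + aa + seq[pos - off + 1 :]
            rows.append(
                {
                    "peptide_id": f"p{pos}{parent_aa}{aa}",
                    "kind": kind,
                    "position": pos,
                    "residue": aa,
                    "trunc_last": pd.NA,
                    "sequence": mutated,
                }
            )
    for last in design.truncations:
        rows.append(
            {
                "peptide_id": f"trunc{last}",
                "kind": "truncation",
                "position": pd.NA,
                "residue": pd.NA,
                "trunc_last": last,
                "sequence": design.truncated_sequence(last),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SubstitutionArrayDataset:
    """Replicated fluorescence signals for every peptide on an array.

    ``signals`` has one row per replicate per peptide with columns
    ``peptide_id, kind, position, residue, trunc_last, replicate, signal``.
    """

    design: ArrayDesign
    signals: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"peptide_id", "kind", "position", "residue", "trunc_last", "replicate", "signal"}
        missing = required - set(self.signals.columns)
        if missing:
            raise ValueError(f"signals table missing columns: {sorted(missing)}")
        if (self.signals["signal"] < 0).any():
            raise ValueError("negative fluorescence signals")
        cells = self.signals[self.signals["kind"].isin(["substitution", "parent"])]
        counts = cells.groupby(["position", "residue"], observed=True).size()
        expected = len(self.design.positions) * len(self.design.alphabet)
        if len(counts) < expected:
            raise ValueError("every (position, residue) cell needs at least one replicate")

    @property
    def substitution_signals(self) -> pd.DataFrame:
        return self.signals[self.signals["kind"].isin(["substitution", "parent"])]

    @property
    def truncation_signals(self) -> pd.DataFrame:
        return self.signals[self.signals["kind"] == "truncation"]


@dataclass
class NormalizedMatrix:
    """Parent-normalized array summary: position x residue, percent of parent."""

    mean_pct: pd.DataFrame
    sd_pct: pd.DataFrame
    n: pd.DataFrame
    design: ArrayDesign


def _parent_means(data: SubstitutionArrayDataset, floor: float) -> pd.Series:
    sub = data.substitution_signals
    design = data.design
    means = {}
    for pos in design.positions:
        parent_aa = design.parent_residue(pos)
        cell = sub[(sub["position"] == pos) & (sub["residue"] == parent_aa)]["signal"]
        m = float(cell.mean())
        if not np.isfinite(m) or m <= floor:
            raise ParentSignalError(
                f"parent-residue signal at position {pos} ({parent_aa}) is "
                f"{m:g}, at or below the floor {floor:g}"
            )
        means[pos] = m
    return pd.Series(means, name="parent_mean")


def normalize_to_parent(
    data: SubstitutionArrayDataset, parent_floor: float = 1e-9
) -> NormalizedMatrix:
    """Express every cell as percent of the parent residue at its position.

    Each replicate value is divided by the pooled mean of the parent-residue
    cell at the same position and scaled to percent; the per-cell mean and
    standard deviation (percentage points, across all replicates) are
    reported.  The parent cell itself therefore has mean exactly 100 with an
    SD equal to its own replicate scatter.
    """
    design = data.design
    parent_means = _parent_means(data, parent_floor)
    sub = data.substitution_signals.copy()
    sub["pct"] = 100.0 * sub["signal"] / sub["position"].map(parent_means)

    grouped = sub.groupby(["position", "residue"], observed=True)["pct"]
    alphabet = list(design.alphabet)
    positions = list(design.positions)
    mean_pct = grouped.mean().unstack().reindex(index=positions, columns=alphabet)
    sd_pct = grouped.std(ddof=1).unstack().reindex(index=positions, columns=alphabet)
    n = grouped.size().unstack().reindex(index=positions, columns=alphabet)
    sd_pct = sd_pct.fillna(0.0)  # single-replicate cells have no scatter
    # pin the parent cells at exactly 100 (they equal it up to float round-off)
    for pos in positions:
        mean_pct.loc[pos, design.parent_residue(pos)] = 100.0
    return NormalizedMatrix(mean_pct=mean_pct, sd_pct=sd_pct, n=n, design=design)


@lru_cache(maxsize=16)
def _studentized_range_grid(k: int, df: int) -> tuple[np.ndarray, np.ndarray]:
    # survival function of the studentized range on a fixed q grid; evaluated
    # once per (number of groups, error dof) and interpolated thereafter —
    # direct evaluation is far too slow to repeat per contrast
    from scipy.stats import studentized_range

    q_grid = np.concatenate([np.linspace(0.0, 10.0, 201), np.linspace(10.2, 30.0, 100)])
    with np.errstate(all="ignore"):
        sf = studentized_range.sf(q_grid, k, df)
    sf = np.clip(sf, 1e-300, 1.0)
    return q_grid, np.log(sf)


def _studentized_range_sf(q: float, k: int, df: int) -> float:
    """Tukey-adjusted p for a studentized-range statistic, grid-interpolated.

    Accurate to ~1e-4 in p over the decision-relevant range; beyond the grid
    the p-value is pinned to its boundary value.
    """
    grid, log_sf = _studentized_range_grid(k, min(df, 100_000))
    return float(np.exp(np.interp(q, grid, log_sf)))


@dataclass
class SignificanceTable:
    """Per-(position, residue) substitution-effect calls.

    ``table`` columns: ``position, residue, mean_diff_pct, direction, p_adj,
    significant``; ``anova`` is the two-way (position x residue) ANOVA table,
    None when testing was refused for lack of replication.
    """

    table: pd.DataFrame
    alpha: float
    anova: pd.DataFrame | None = None
    descriptive_only: bool = False

    def lookup(self, position: int, residue: str) -> pd.Series:
        t = self.table
        row = t[(t["position"] == position) & (t["residue"] == residue)]
        if row.empty:
            raise KeyError((position, residue))
        return row.iloc[0]


def test_substitution_effects(
    data: SubstitutionArrayDataset,
    alpha: float = 0.05,
    on: str = "normalized",
    parent_floor: float = 1e-9,
) -> SignificanceTable:
    """Call significant substitution effects against the parent residue.

    Runs a two-way ANOVA (position x substituted residue) on the replicate
    values, then, within each position, Tukey HSD contrasts of every
    substitution against the parent residue ("simple effect within
    columns").  Direction is the sign of the mean difference.

    With ``on="normalized"`` (default) replicate values are first divided by
    the pooled parent mean at their position; ``on="raw"`` tests raw
    fluorescence.

    With a single replicate per cell no inference is possible: a descriptive
    table (all ``significant`` False, ``p_adj`` NaN) is returned with a
    warning.
    """
    if on not in {"normalized", "raw"}:
        raise ValueError(f"unknown data scale {on!r}")
    design = data.design
    sub = data.substitution_signals.copy()
    if on == "normalized":
        parent_means = _parent_means(data, parent_floor)
        sub["value"] = 100.0 * sub["signal"] / sub["position"].map(parent_means)
    else:
        sub["value"] = sub["signal"].astype(float)

    counts = sub.groupby(["position", "residue"], observed=True).size()
    rows = []
    if counts.min() < 2:
        warnings.warn(
            "single replicate per cell: significance testing refused, "
            "returning a descriptive table",
            UserWarning,
            stacklevel=2,
        )
        for pos in design.positions:
            parent_aa = design.parent_residue(pos)
            at_pos = sub[sub["position"] == pos]
            parent_mean = at_pos[at_pos["residue"] == parent_aa]["value"].mean()
            for aa in design.alphabet:
                if aa == parent_aa:
                    continue
                diff = at_pos[at_pos["residue"] == aa]["value"].mean() - parent_mean
                rows.append(
                    {
                        "position": pos,
                        "residue": aa,
                        "mean_diff_pct": diff,
                        "direction": "increase" if diff > 0 else "decrease",
                        "p_adj": np.nan,
                        "significant": False,
                    }
                )
        return SignificanceTable(pd.DataFrame(rows), alpha=alpha, descriptive_only=True)

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols("value ~ C(position) * C(residue)", data=sub).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance null designs trip F-dof warnings
        anova = anova_lm(model, typ=2)

    for pos in design.positions:
        parent_aa = design.parent_residue(pos)
        at_pos = sub[sub["position"] == pos]
        grouped = at_pos.groupby("residue", observed=True)["value"]
        means = grouped.mean()
        ns = grouped.size()
        variances = grouped.var(ddof=1)
        k = len(means)
        df_err = int(ns.sum() - k)
        mse = float(((ns - 1) * variances).sum() / df_err)
        for aa in design.alphabet:
            if aa == parent_aa:
                continue
            diff = float(means[aa] - means[parent_aa])
            se = math.sqrt(mse / 2.0 * (1.0 / ns[aa] + 1.0 / ns[parent_aa])) if mse > 0 else 0.0
            if se > 0:
                q = abs(diff) / se
                p = _studentized_range_sf(q, k, df_err)
            else:
                # zero within-cell scatter: the difference is deterministic
                p = 1.0 if diff == 0.0 else 0.0
            rows.append(
                {
                    "position": pos,
                    "residue": aa,
                    "mean_diff_pct": diff,
                    "direction": "increase" if diff > 0 else "decrease",
                    "p_adj": float(p),
                    "significant": bool(p < alpha),
                }
            )
    table = pd.DataFrame(rows).sort_values(["position", "residue"]).reset_index(drop=True)
    return SignificanceTable(table, alpha=alpha, anova=anova)


CHARGE_RESIDUES = ("R", "K")


def classify_positions(
    matrix: NormalizedMatrix,
    table: SignificanceTable,
    essential_floor: float = 20.0,
    essential_fraction: float = 0.8,
) -> pd.Series:
    """Assign each position a category from its substitution tolerance.

    essential
        At least ``essential_fraction`` of the non-parent substitutions
        (Arg/Lys exempted, since a positive charge can rescue binding by a
        different mechanism) fall below ``essential_floor`` percent of
        parent *and* are flagged significant decreases.
    charge-enhanced
        Arg and/or Lys substitutions are flagged significant increases.
    mixed
        Any other significant effect.
    tolerant
        No significant effect.
    """
    design = matrix.design
    t = table.table
    categories = {}
    for pos in design.positions:
        parent_aa = design.parent_residue(pos)
        at_pos = t[t["position"] == pos]
        flagged = at_pos[at_pos["significant"]]
        candidates = [aa for aa in design.alphabet if aa != parent_aa and aa not in CHARGE_RESIDUES]
        n_essential = 0
        for aa in candidates:
            below = matrix.mean_pct.loc[pos, aa] < essential_floor
            row = at_pos[at_pos["residue"] == aa]
            flagged_dec = (
                not row.empty and bool(row.iloc[0]["significant"]) and row.iloc[0]["direction"] == "decrease"
            )
            if below and flagged_dec:
                n_essential += 1
        charge_up = not flagged[
            flagged["residue"].isin(CHARGE_RESIDUES) & (flagged["direction"] == "increase")
        ].empty
        if candidates and n_essential / len(candidates) >= essential_fraction:
            categories[pos] = "essential"
        elif charge_up:
            categories[pos] = "charge-enhanced"
        elif not flagged.empty:
            categories[pos] = "mixed"
        else:
            categories[pos] = "tolerant"
    return pd.Series(categories, name="category")


def truncation_boundary(
    data: SubstitutionArrayDataset, loss_threshold: float = 20.0
) -> int | None:
    """Locate the most C-terminal position whose removal abolishes binding.

    Mean truncation-peptide signals are expressed as percent of the longest
    (full-length) truncation peptide and scanned from full length towards
    the N terminus; the boundary is the last-retained position just above
    the first truncation that falls below ``loss_threshold`` percent — i.e.
    the most C-terminal position whose removal drops the signal below the
    threshold.  Returns None when no truncation crosses the threshold.
    """
    trunc = data.truncation_signals
    if trunc.empty:
        raise ValueError("dataset contains no truncation peptides")
    means = trunc.groupby("trunc_last")["signal"].mean().sort_index(ascending=False)
    full_mean = means.iloc[0]
    if full_mean <= 0:
        raise ParentSignalError("full-length truncation peptide has non-positive mean signal")
    pct = 100.0 * means / full_mean
    lasts = list(pct.index)
    for prev_last, last in zip(lasts, lasts[1:]):
        if pct[last] < loss_threshold:
            return int(prev_last)
    return None
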