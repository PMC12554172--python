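"""Equilibrium binding analysis for two-channel SPR data.

An SPR experiment flows analyte at increasing concentrations over a
reference flow cell (Fc1, blank surface) and a measurement flow cell (Fc2,
ligand-coated).  The equilibrium response of the reference channel is
subtracted per concentration to give the specific response, which is fit
with a one-site Langmuir saturation model

    R(C) = Bmax * C / (K_D + C)

to estimate the equilibrium dissociation constant K_D (μM) and the maximal
response Bmax (RU).  A rank-based monotonic dose-response check for
dot-blot series is also provided.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class ChannelAlignmentError(ValueError):
    """Reference and measurement channels are not on the same concentration grid."""


class FitConvergenceError(RuntimeError):
    """The nonlinear saturation fit failed to converge."""


def twofold_series(low: float = 0.29, high: float = 75.0) -> np.ndarray:
    """Two-fold dilution series from ``high`` down to approximately ``low``.

    The default reproduces a 9-point series from 75 μM down to 0.29 μM
    (75 / 2^8 ≈ 0.293), returned in increasing order.
    """
    n = int(round(math.log2(high / low))) + 1
    return high / 2.0 ** np.arange(n)[::-1]


@dataclass
class BindingIsotherm:
    """Equilibrium responses over an analyte concentration series.

    ``data`` columns: ``concentration_uM`` plus ``ru_fc1`` (reference) and
    ``ru_fc2`` (measurement), and/or ``ru_specific`` after subtraction.
    Concentrations must be strictly positive and strictly increasing.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "concentration_uM" not in self.data.columns:
            raise ValueError("isotherm needs a concentration_uM column")
        c = self.data["concentration_uM"].to_numpy(dtype=float)
        if (c <= 0).any():
            raise ValueError("concentrations must be strictly positive")
        if (np.diff(c) <= 0).any():
            raise ValueError("concentrations must be strictly increasing")
        has_channels = {"ru_fc1", "ru_fc2"} <= set(self.data.columns)
        if not has_channels and "ru_specific" not in self.data.columns:
            raise ValueError("isotherm needs ru_fc1/ru_fc2 channels or ru_specific")

    @property
    def concentrations(self) -> np.ndarray:
        return self.data["concentration_uM"].to_numpy(dtype=float)

    @property
    def specific(self) -> np.ndarray:
        if "ru_specific" not in self.data.columns:
            raise ValueError("no specific response; run reference_subtract first")
        return self.data["ru_specific"].to_numpy(dtype=float)


def reference_subtract(isotherm: BindingIsotherm) -> BindingIsotherm:
    """Subtract the reference-channel response per concentration.

    ``specific = ru_fc2 - ru_fc1`` row by row.  Negative specific responses
    are retained (and flagged with a warning), never clipped: they carry
    information about over-subtraction.
    """
    df = isotherm.data
    if not {"ru_fc1", "ru_fc2"} <= set(df.columns):
        raise ChannelAlignmentError("both ru_fc1 and ru_fc2 are required at every concentration")
    if df[["ru_fc1", "ru_fc2"]].isna().any().any():
        raise ChannelAlignmentError("channels are misaligned: missing responses on the grid")
    out = df.copy()
    out["ru_specific"] = out["ru_fc2"] - out["ru_fc1"]
    n_neg = int((out["ru_specific"] < 0).sum())
    if n_neg:
        warnings.warn(
            f"{n_neg} negative specific response(s) after reference subtraction",
            UserWarning,
            stacklevel=2,
        )
    return BindingIsotherm(out)


@dataclass
class SaturationFit:
    """One-site saturation fit result."""

    kd_uM: float
    bmax_RU: float
    kd_ci: tuple[float, float]
    bmax_ci: tuple[float, float]
    residuals: np.ndarray
    covariance: np.ndarray
    n_points: int
    poorly_constrained: bool = False

    def predict(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.bmax_RU * conc / (self.kd_uM + conc)

    @property
    def half_saturation_uM(self) -> float:
        """Concentration at half-maximal response; identical to K_D for this model."""
        return self.kd_uM


def _langmuir(c: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    return bmax * c / (kd + c)


def fit_saturation(
    isotherm: BindingIsotherm,
    weights: np.ndarray | None = None,
    ci_level: float = 0.95,
) -> SaturationFit:
    """Fit the one-site saturation model to specific equilibrium responses.

    Unweighted least squares by default; pass per-point standard deviations
    as ``weights`` for 1/variance weighting.  Confidence intervals come from
    the parameter covariance with a t quantile on n-2 degrees of freedom.
    A warning is raised when the estimated K_D falls outside
    [min(C)/10, max(C)*10] — the data then barely constrain it.
    """
    c = isotherm.concentrations
    r = isotherm.specific
    if len(c) < 4:
        raise ValueError("need at least 4 concentrations")
    if c.max() / c.min() < 10.0:
        raise ValueError("concentration series must span at least one decade")
    p0 = (max(r.max(), 1e-6), float(np.median(c)))
    try:
        popt, pcov = optimize.curve_fit(
            _langmuir,
            c,
            r,
            p0=p0,
            sigma=weights,
            absolute_sigma=False,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitConvergenceError(f"saturation fit did not converge: {exc}") from exc
    bmax, kd = popt
    resid = r - _langmuir(c, *popt)
    dof = max(len(c) - 2, 1)
    tq = stats.t.ppf(0.5 + ci_level / 2.0, dof)
    se_bmax, se_kd = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    poorly = not (c.min() / 10.0 <= kd <= c.max() * 10.0)
    if poorly:
        warnings.warn(
            f"K_D estimate {kd:.3g} μM lies outside the concentration span; "
            "the fit is poorly constrained",
            UserWarning,
            stacklevel=2,
        )
    return SaturationFit(
        kd_uM=float(kd),
        bmax_RU=float(bmax),
        kd_ci=(float(kd - tq * se_kd), float(kd + tq * se_kd)),
        bmax_ci=(float(bmax - tq * se_bmax), float(bmax + tq * se_bmax)),
        residuals=resid,
        covariance=pcov,
        n_points=len(c),
        poorly_constrained=poorly,
    )


@dataclass
class DoseResponseResult:
    """Monotonic dose-response verdict for a dilution series."""

    statistic: float
    p_value: float
    verdict: str  # dose-dependent | flat | ambiguous
    n_levels: int


def dose_response_check(
    amounts: np.ndarray,
    intensities: np.ndarray,
    alpha: float = 0.05,
    exact_max_n: int = 8,
) -> DoseResponseResult:
    """Rank-correlation test for a monotonically increasing dose response.

    Spearman rho between spotted amount and signal intensity, with a
    one-sided (increasing) p-value: exact by permutation enumeration for up
    to ``exact_max_n`` dose levels, asymptotic beyond.  Verdict:
    ``dose-dependent`` when rho >= 0.8, ``flat`` when rho <= 0.2 or the
    intensities are constant, ``ambiguous`` otherwise; the p-value is
    reported alongside (with few dose levels it is necessarily coarse).
    """
    amounts = np.asarray(amounts, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if len(amounts) != len(intensities):
        raise ValueError("amounts and intensities must have equal length")
    n = len(amounts)
    if n < 3:
        raise ValueError("need at least 3 dose levels")
    if np.ptp(intensities) == 0.0:
        return DoseResponseResult(np.nan, np.nan, "flat", n)
    rho = stats.spearmanr(amounts, intensities).statistic
    if n <= exact_max_n:
        # exact one-sided permutation null over all orderings of the intensities;
        # Spearman rho is the Pearson correlation of the ranks, computed for all
        # n! permutations in one vectorized pass
        ra = stats.rankdata(amounts)
        ri = stats.rankdata(intensities)
        perms = np.array(list(itertools.permutations(range(n))))
        permuted = ri[perms]
        ra_c = ra - ra.mean()
        perm_c = permuted - permuted.mean(axis=1, keepdims=True)
        denom = np.sqrt((ra_c**2).sum() * (perm_c**2).sum(axis=1))
        rho_all = (perm_c @ ra_c) / denom
        p = float(np.mean(rho_all >= rho - 1e-12))
    else:
        p = stats.spearmanr(amounts, intensities, alternative="greater").pvalue
    if rho >= 0.8:
        verdict = "dose-dependent"
    elif rho <= 0.2:
        verdict = "flat"
    else:
        verdict = "ambiguous"
    return DoseResponseResult(float(rho), float(p), verdict, n)
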