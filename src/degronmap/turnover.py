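"""Protein-turnover quantification from densitometry readouts.

Covers the standard immunoblot quantification chain: normalization of band
intensities to a loading control (β-actin) and a reference condition,
co-immunoprecipitation association expressed as percent of wild type,
single-exponential half-life fits to translation-arrest (cycloheximide
chase) decay courses, and factorial genotype x treatment stabilization
comparisons (two-way ANOVA with Tukey or Bonferroni post hoc tests).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LN2 = float(np.log(2.0))


class NormalizationError(ValueError):
    """A loading-control or reference value makes normalization impossible."""


class NoDecayError(ValueError):
    """The fitted decay rate is not positive — no decay detected."""


def normalize_densitometry(
    table: pd.DataFrame,
    reference_condition: str | None = None,
    reference_timepoint: float | None = None,
) -> pd.DataFrame:
    """Normalize band intensities to the loading control and a reference.

    Each row's ``band`` is divided by its ``loading`` (e.g. β-actin) lane;
    the ratios are then scaled so the mean ratio of the reference rows
    (selected by ``reference_condition`` and/or ``reference_timepoint``; all
    rows with timepoint 0 when neither is given and a ``timepoint_min``
    column exists) equals 100%.  Returns a copy with ``ratio`` and
    ``normalized_pct`` columns.
    """
    required = {"band", "loading"}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    zero = table.index[table["loading"] <= 0]
    if len(zero):
        raise NormalizationError(f"non-positive loading control in row(s) {list(zero)}")
    out = table.copy()
    out["ratio"] = out["band"] / out["loading"]
    mask = pd.Series(True, index=out.index)
    if reference_condition is not None:
        mask &= out["condition"] == reference_condition
    if reference_timepoint is not None:
        mask &= out["timepoint_min"] == reference_timepoint
    if reference_condition is None and reference_timepoint is None and "timepoint_min" in out:
        mask &= out["timepoint_min"] == 0
    if not mask.any():
        raise NormalizationError("no rows match the reference condition/timepoint")
    ref = float(out.loc[mask, "ratio"].mean())
    if ref <= 0:
        raise NormalizationError("reference ratio is non-positive")
    out["normalized_pct"] = 100.0 * out["ratio"] / ref
    return out


def coip_association(
    table: pd.DataFrame,
    wt_label: str = "WT",
    control_labels: tuple[str, ...] = ("IgG",),
) -> pd.DataFrame:
    """Co-IP association per condition as percent of wild type.

    Each sample's immunoprecipitated intensity (``ip``) is divided by its
    input lane (``input``) and the ratios scaled so the wild-type mean is
    100%.  Negative-control lanes (``control_labels``, e.g. IgG pulldowns)
    are excluded from the scaling but reported on the same scale.

    Returns a copy with an ``association_pct`` column.
    """
    required = {"condition", "ip", "input"}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    if not (table["condition"] == wt_label).any():
        raise ValueError(f"wild-type condition {wt_label!r} missing")
    zero = table.index[table["input"] <= 0]
    if len(zero):
        raise NormalizationError(f"non-positive input intensity in row(s) {list(zero)}")
    out = table.copy()
    out["ip_over_input"] = out["ip"] / out["input"]
    wt_mean = float(out.loc[out["condition"] == wt_label, "ip_over_input"].mean())
    if wt_mean <= 0:
        raise NormalizationError("wild-type IP/input mean is non-positive")
    out["association_pct"] = 100.0 * out["ip_over_input"] / wt_mean
    out["is_control"] = out["condition"].isin(control_labels)
    return out


@dataclass
class DecayCourse:
    """Loading-normalized abundance versus time after translation arrest.

    ``data`` columns: ``timepoint_min, replicate, abundance_pct`` (percent
    of t=0, which must be present and equal 100 per replicate).
    """

    data: pd.DataFrame
    condition: str = ""

    def __post_init__(self) -> None:
        required = {"timepoint_min", "replicate", "abundance_pct"}
        if not required <= set(self.data.columns):
            raise ValueError(f"decay course needs columns {sorted(required)}")
        t0 = self.data[self.data["timepoint_min"] == 0]
        if t0.empty:
            raise ValueError("decay course must include timepoint 0")
        if not np.allclose(t0["abundance_pct"], 100.0):
            raise ValueError("abundance at t=0 must equal 100% by construction")


@dataclass
class DecayFit:
    """Single-exponential decay fit: N(t) = N0 * 2^(-t / t_half)."""

    k_per_min: float
    t_half_min: float
    t_half_ci: tuple[float, float]
    r_squared: float
    n_points: int
    method: str
    aic: float | None = None

    def predict(self, t: np.ndarray) -> np.ndarray:
        return 100.0 * np.exp(-self.k_per_min * np.asarray(t, dtype=float))


def fit_decay(
    course: DecayCourse, method: str = "log-linear", ci_level: float = 0.95
) -> DecayFit:
    """Estimate the protein half-life from a chase decay course.

    ``log-linear`` (default) regresses ln(abundance) on time with a free
    intercept — the slope gives k and is unbiased under multiplicative
    noise, including the correlation introduced by normalizing every
    replicate to its own t=0 point.  ``nonlinear`` fits
    ``N0 * exp(-k t)`` on the raw percent scale instead.  In both cases
    ``t_half = ln 2 / k`` with a CI propagated from the k interval.
    """
    df = course.data
    t = df["timepoint_min"].to_numpy(dtype=float)
    y = df["abundance_pct"].to_numpy(dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct timepoints")
    if method == "log-linear":
        keep = y > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} non-positive abundance value(s) before log fit",
                UserWarning,
                stacklevel=2,
            )
        t_fit, ly = t[keep], np.log(y[keep])
        res = stats.linregress(t_fit, ly)
        k = -res.slope
        se_k = res.stderr
        dof = len(t_fit) - 2
        r2 = res.rvalue**2
    elif method == "nonlinear":
        from scipy.optimize import curve_fit

        popt, pcov = curve_fit(
            lambda tt, n0, kk: n0 * np.exp(-kk * tt), t, y, p0=(100.0, 0.03), maxfev=10000
        )
        k = popt[1]
        se_k = float(np.sqrt(max(pcov[1, 1], 0.0)))
        dof = len(t) - 2
        ss_res = float(np.sum((y - popt[0] * np.exp(-k * t)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    if k <= 0:
        raise NoDecayError(f"no decay detected (k = {k:.3g} per min)")
    tq = stats.t.ppf(0.5 + ci_level / 2.0, max(dof, 1))
    k_lo, k_hi = k - tq * se_k, k + tq * se_k
    ci = (LN2 / k_hi if k_hi > 0 else np.inf, LN2 / k_lo if k_lo > 0 else np.inf)
    return DecayFit(
        k_per_min=float(k),
        t_half_min=float(LN2 / k),
        t_half_ci=(float(min(ci)), float(max(ci))),
        r_squared=float(r2),
        n_points=int(len(t)),
        method=method,
    )


@dataclass
class StabilizationResult:
    """Factorial stabilization comparison."""

    anova: pd.DataFrame | None
    pairwise: pd.DataFrame
    alpha: float
    design: str  # factorial | two-group


def compare_stabilization(
    table: pd.DataFrame,
    alpha: float = 0.05,
    posthoc: str = "tukey",
    value_col: str = "value",
) -> StabilizationResult:
    """Compare normalized levels across a genotype x treatment design.

    For a full factorial design, fits a two-way ANOVA (main effects and
    interaction) and runs post hoc pairwise comparisons across the
    genotype:treatment cells — Tukey HSD by default, Bonferroni-adjusted
    Welch t tests when ``posthoc="bonferroni"``.  A degenerate single-factor
    two-group table falls back to an unpaired Student's t test.
    """
    required = {"genotype", "treatment", value_col}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    if posthoc not in {"tukey", "bonferroni"}:
        raise ValueError(f"unknown post hoc method {posthoc!r}")
    df = table.copy()
    counts = df.groupby(["genotype", "treatment"], observed=True)[value_col].size()
    geno = df["genotype"].unique()
    treat = df["treatment"].unique()
    for g in geno:
        for tr in treat:
            if (g, tr) not in counts.index:
                raise ValueError(f"empty design cell: genotype={g!r}, treatment={tr!r}")
    if counts.min() < 2:
        raise ValueError("need >= 2 replicates per cell")

    if len(geno) * len(treat) == 2:  # single varying factor, two groups
        factor = "genotype" if len(geno) == 2 else "treatment"
        a, b = sorted(df[factor].unique())
        va = df.loc[df[factor] == a, value_col]
        vb = df.loc[df[factor] == b, value_col]
        t, p = stats.ttest_ind(va, vb)
        pairwise = pd.DataFrame(
            [
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_diff": float(vb.mean() - va.mean()),
                    "p_adj": float(p),
                    "significant": bool(p < alpha),
                }
            ]
        )
        return StabilizationResult(anova=None, pairwise=pairwise, alpha=alpha, design="two-group")

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = df.rename(columns={value_col: "value"})
    model = smf.ols("value ~ C(genotype) * C(treatment)", data=df).fit()
    anova = anova_lm(model, typ=2)

    df["cell"] = df["genotype"].astype(str) + ":" + df["treatment"].astype(str)
    rows = []
    if posthoc == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tuk = pairwise_tukeyhsd(df["value"].to_numpy(), df["cell"].to_numpy(), alpha=alpha)
        cells = list(tuk.groupsunique)
        for (g1, g2), p, rej, diff in zip(
            itertools.combinations(cells, 2), tuk.pvalues, tuk.reject, tuk.meandiffs
        ):
            rows.append(
                {
                    "group_a": g1,
                    "group_b": g2,
                    "mean_diff": float(diff),
                    "p_adj": float(p),
                    "significant": bool(rej),
                }
            )
    else:
        cells = sorted(df["cell"].unique())
        combos = list(itertools.combinations(cells, 2))
        for g1, g2 in combos:
            va = df.loc[df["cell"] == g1, "value"]
            vb = df.loc[df["cell"] == g2, "value"]
            _, p = stats.ttest_ind(va, vb, equal_var=False)
            p_adj = min(1.0, p * len(combos))
            rows.append(
                {
                    "group_a": g1,
                    "group_b": g2,
                    "mean_diff": float(vb.mean() - va.mean()),
                    "p_adj": float(p_adj),
                    "significant": bool(p_adj < alpha),
                }
            )
    return StabilizationResult(
        anova=anova, pairwise=pd.DataFrame(rows), alpha=alpha, design="factorial"
    )
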