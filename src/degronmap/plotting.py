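"""Figure helpers: substitution heatmaps, contact maps, binding and decay curves."""

from __future__ import annotations

import numpy as np

from .arrays import NormalizedMatrix
from .binding import BindingIsotherm, SaturationFit
from .trajectory import ContactMap, RMSDAggregate
from .turnover import DecayCourse, DecayFit


def substitution_heatmap(matrix: NormalizedMatrix, ax=None, vmax: float = 200.0):
    """Position x residue heatmap of percent-of-parent signal.

    The color scale is fixed to 0-``vmax`` percent with overflow binned at
    the top color, since enhancement cells exceed 100%.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    data = np.minimum(matrix.mean_pct.to_numpy(dtype=float), vmax)
    im = ax.imshow(data.T, aspect="auto", cmap="viridis", vmin=0.0, vmax=vmax)
    ax.set_xticks(range(len(matrix.mean_pct.index)), matrix.mean_pct.index)
    ax.set_yticks(range(len(matrix.mean_pct.columns)), matrix.mean_pct.columns)
    ax.set_xlabel("parent position")
    ax.set_ylabel("substituted residue")
    ax.figure.colorbar(im, ax=ax, label="% of parent signal")
    return ax


def contact_map_heatmap(cmap: ContactMap, ax=None):
    """Contact-frequency heatmap, receptor residues on x, peptide on y."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    # freq rows are receptor residues; transpose to put receptor on x
    im = ax.imshow(
        cmap.freq.to_numpy().T, aspect="auto", cmap="inferno", vmin=0.0, vmax=1.0, origin="lower"
    )
    ax.set_xlabel("receptor residue")
    ax.set_ylabel("peptide residue")
    ax.set_title(f"pose {cmap.pose} ({cmap.n_trials} trials)")
    ax.figure.colorbar(im, ax=ax, label="contact frequency")
    return ax


def rmsd_plot(aggregates: dict[int, RMSDAggregate], frame_spacing_ps: float = 10.0, ax=None):
    """Mean RMSD lines with variance shading, one color per pose."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for pose, agg in sorted(aggregates.items()):
        t = np.arange(len(agg.mean)) * frame_spacing_ps / 1000.0
        ax.plot(t, agg.mean, label=f"pose {pose}")
        ax.fill_between(t, agg.mean - agg.variance, agg.mean + agg.variance, alpha=0.25)
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("RMSD (nm)")
    ax.legend()
    return ax


def saturation_plot(isotherm: BindingIsotherm, fit: SaturationFit, ax=None):
    """Specific response vs concentration with the fitted curve and K_D marker."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    c = isotherm.concentrations
    ax.plot(c, isotherm.specific, "o", label="specific response")
    grid = np.linspace(0.0, c.max() * 1.05, 300)
    ax.plot(grid, fit.predict(grid), "-", label="one-site fit")
    ax.axvline(fit.kd_uM, linestyle=":", color="gray", label=f"$K_D$ = {fit.kd_uM:.2g} μM")
    ax.set_xlabel("concentration (μM)")
    ax.set_ylabel("response (RU)")
    ax.legend()
    return ax


def decay_plot(course: DecayCourse, fit: DecayFit | None = None, ax=None):
    """Chase decay points with the fitted exponential and half-life annotation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    df = course.data
    for rep, grp in df.groupby("replicate"):
        ax.plot(grp["timepoint_min"], grp["abundance_pct"], "o", alpha=0.6)
    if fit is not None:
        t = np.linspace(0.0, df["timepoint_min"].max(), 200)
        ax.plot(t, fit.predict(t), "-", label=f"$t_{{1/2}}$ = {fit.t_half_min:.1f} min")
        ax.legend()
    ax.set_xlabel("time after translation arrest (min)")
    ax.set_ylabel("abundance (% of t=0)")
    if course.condition:
        ax.set_title(course.condition)
    return ax
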