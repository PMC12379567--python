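"""Concentration time-course plots: median with quantile band, dietary-only
reference as a dotted line, tissue threshold as a dashed line, and shading
over the treatment window."""

from __future__ import annotations

import numpy as np

from .assessment import ULN_WW
from .dosing import DAYS_PER_YEAR


def plot_timecourse(
    prun,
    tissue: str,
    ax=None,
    baseline=None,
    show_uln: bool = True,
    scenario=None,
):
    """Plot median and p5-p95 band of one tissue for a population run.

    ``baseline`` (another PopulationRun, e.g. dietary-only) adds its median
    as a dotted reference; ``scenario`` shades the SCIT treatment window(s).
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ages = prun.age_years
    mat = prun.concentrations(tissue)
    p5, med, p95 = np.quantile(mat, [0.05, 0.5, 0.95], axis=0)
    ax.fill_between(ages, p5, p95, alpha=0.3, lw=0, label="p5-p95")
    ax.plot(ages, med, lw=1.5, label="median")
    if baseline is not None:
        base_med = np.median(baseline.concentrations(tissue), axis=0)
        ax.plot(baseline.age_years, base_med, ls=":", color="k", lw=1.0,
                label="dietary only (median)")
    if show_uln and tissue in ULN_WW:
        ax.axhline(ULN_WW[tissue], ls="--", color="k", lw=0.8, label="ULN")
    if scenario is not None:
        for block in getattr(scenario, "scit_blocks", ()):
            ax.axvspan(
                block.start_age_y,
                block.end_day / DAYS_PER_YEAR,
                color="grey",
                alpha=0.15,
                lw=0,
            )
    unit = "ug/L" if tissue == "plasma" else "ug/g ww"
    ax.set_xlabel("age (years)")
    ax.set_ylabel(f"Al in {tissue} ({unit})")
    ax.legend(frameon=False, fontsize=8)
    return ax
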