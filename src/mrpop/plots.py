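"""Optional plotting hooks: population pyramids and fan charts.

Matplotlib is imported lazily so headless/batch use of the package never
requires a display or the plotting stack.
"""

from __future__ import annotations

import numpy as np

from .core_data import DimensionRegistry
from .projection import PopulationForecast
from .summaries import summarize_draws


def population_pyramid(
    pf: PopulationForecast, year: int, path: str, region: str | None = None
):
    """Median pyramid with 95% interval whiskers for one period.

    ``region=None`` aggregates all regions.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reg = pf.registry
    t = pf.years.index(year)
    values = pf.values[:, t]
    if region is not None:
        values = values[:, reg.regions.index(region)][:, None]
    by_age_sex = values.sum(axis=1)  # (ndraw, z, 2)
    s = summarize_draws(by_age_sex.reshape(by_age_sex.shape[0], -1))
    med = np.asarray(s.median).reshape(reg.n_ages, 2)
    lo, hi = (np.asarray(v).reshape(reg.n_ages, 2) for v in s.interval(0.95))

    fig, ax = plt.subplots(figsize=(7, 6))
    y = np.arange(reg.n_ages)
    ax.barh(y, -med[:, 0], color="#4878b0", label="males")
    ax.barh(y, med[:, 1], color="#b04878", label="females")
    ax.errorbar(-med[:, 0], y, xerr=[med[:, 0] - lo[:, 0], hi[:, 0] - med[:, 0]],
                fmt="none", ecolor="k", elinewidth=0.8)
    ax.errorbar(med[:, 1], y, xerr=[med[:, 1] - lo[:, 1], hi[:, 1] - med[:, 1]],
                fmt="none", ecolor="k", elinewidth=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels([f"{a}+" if i == reg.n_ages - 1 else f"{a}-{a + 4}"
                        for i, a in enumerate(reg.age_groups)])
    ax.set_title(f"Population {year}" + (f", {region}" if region else ""))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def totals_fan_chart(pf: PopulationForecast, path: str):
    """Fan chart of total population with 50/80/95% predictive bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    totals = pf.totals()
    s = summarize_draws(totals)
    fig, ax = plt.subplots(figsize=(7, 4))
    x = pf.years
    for lv, alpha in ((0.95, 0.2), (0.8, 0.3), (0.5, 0.4)):
        lo, hi = s.interval(lv)
        ax.fill_between(x, lo, hi, color="#4878b0", alpha=alpha, lw=0)
    ax.plot(x, s.median, color="#1f3a5f", lw=2)
    ax.set_ylabel("total population")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
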