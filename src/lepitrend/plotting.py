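"""Plots of fitted trends and species-level coefficients."""

from __future__ import annotations

import numpy as np

from .trends import ELEVATION_QUANTILES, conditional_trend, elevation_at_quantile


def plot_conditional_trends(fit, elevation_quantiles=ELEVATION_QUANTILES, ax=None,
                            log_scale=True):
    """Trend curves (posterior mean + 95% band) per elevation quantile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    preds = conditional_trend(fit, elevation_quantiles)
    cmap = plt.get_cmap("viridis")
    for i, (q, df) in enumerate(sorted(preds.items())):
        color = cmap(i / max(len(preds) - 1, 1))
        elev = elevation_at_quantile(fit, q)
        ax.plot(df["year"], df["mean"], color=color,
                label=f"{int(100 * q)}% ({elev:.0f} m)")
        ax.fill_between(df["year"], df["ci2.5"], df["ci97.5"], color=color, alpha=0.15)
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("year")
    ax.set_ylabel("expected response")
    ax.legend(title="elevation quantile", fontsize=8)
    return ax


def plot_species_coefficients(coefficients, ax=None):
    """Strip plot of per-species interaction posteriors (sorted by mean),
    with the negative-to-positive crossing marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    coefs = sorted(coefficients, key=lambda c: c.mean)
    x = np.arange(len(coefs))
    means = [c.mean for c in coefs]
    los = [c.ci[0] for c in coefs]
    his = [c.ci[1] for c in coefs]
    ax.vlines(x, los, his, color="0.7", lw=1)
    ax.scatter(x, means, s=12, color="k", zorder=3)
    ax.axhline(0.0, color="0.4", lw=0.8)
    crossing = int(np.sum(np.asarray(means) < 0))
    ax.axvline(crossing - 0.5, color="tab:blue", ls="-", lw=1,
               label=f"sign change (n={crossing})")
    ax.set_xlabel("species (sorted by posterior mean)")
    ax.set_ylabel("year x elevation coefficient")
    ax.legend(fontsize=8)
    return ax
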