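"""Optional plotting of power curves and diagnostic bands (SVG output).

Requires matplotlib; import happens lazily so the core pipeline has no hard
plotting dependency.
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["plot_power_curve", "plot_diagnostic_band"]


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=(6, 4))


def plot_power_curve(curve, path) -> Path:
    """Power versus study size with optional bootstrap confidence band."""
    fig, ax = _axes()
    if curve.ci_low is not None and curve.ci_high is not None:
        ax.fill_between(curve.sizes, curve.ci_low, curve.ci_high,
                        alpha=0.3, color="gray", label="95% bootstrap CI")
    ax.plot(curve.sizes, curve.power, "k.-", label="PPE power")
    ax.axhline(0.8, ls=":", lw=0.8, color="gray")
    ax.set_xlabel("study size N")
    ax.set_ylabel("power")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    path = Path(path)
    fig.savefig(path, format="svg", bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)
    return path


def plot_diagnostic_band(band, path) -> Path:
    """Bootstrap CDF confidence band overlaid with the observed ECDF."""
    fig, ax = _axes()
    ax.fill_between(band.t_grid, band.band_low, band.band_high,
                    alpha=0.3, color="gray", label="95% CDF band")
    ax.step(band.ecdf_t, band.ecdf, where="post", color="k", label="observed ECDF")
    ax.set_xlabel("test statistic")
    ax.set_ylabel("cumulative probability")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, loc="lower right")
    path = Path(path)
    fig.savefig(path, format="svg", bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)
    return path
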