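"""Visualization of the fitted gene-to-trait effect."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .coloc import InstrumentSet  # noqa: E402
from .slope import SlopeFit  # noqa: E402


def plot_slope(fit: SlopeFit, instruments: InstrumentSet,
               path: str | Path) -> Path:
    """Scatter of instrument effects with the fitted slope and dispersion band.

    Exposure effects on x, outcome effects on y, with standard-error bars;
    the solid line is the posterior-mean slope anchored at the origin, the
    dashed lines the credible-interval slopes, and the shaded band extends
    +/- posterior-mean sigma (the allelic dispersion) around the line.
    """
    path = Path(path)
    ba, sa = instruments.beta_a, instruments.se_a
    bb, sb = instruments.beta_b, instruments.se_b
    lim = 1.1 * max(float(np.max(np.abs(ba) + sa)), 1e-6)
    x = np.linspace(0.0, lim, 50)
    a_hat = fit.alpha_mean
    lo, hi = fit.alpha_interval
    sig = fit.sigma_mean

    figure, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(x, a_hat * x - sig, a_hat * x + sig,
                    color="lightblue", alpha=0.6,
                    label=f"dispersion ±σ̂ = {sig:.3g}")
    ax.plot(x, a_hat * x, color="tab:blue", lw=2,
            label=f"slope α̂ = {a_hat:.3g}")
    ax.plot(x, lo * x, color="tab:blue", lw=1, ls="--")
    ax.plot(x, hi * x, color="tab:blue", lw=1, ls="--",
            label=f"{int(fit.level * 100)}% interval")
    ax.errorbar(ba, bb, xerr=sa, yerr=sb, fmt="o", color="black", ms=4,
                elinewidth=1, capsize=2)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("exposure (eQTL) effect")
    ax.set_ylabel("outcome (GWAS) effect")
    ax.legend(fontsize=8, loc="best")
    figure.tight_layout()
    figure.savefig(path, dpi=150)
    plt.close(figure)
    return path
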