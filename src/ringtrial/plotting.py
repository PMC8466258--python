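"""Simple plots over fitted results: per-platform metabolite level profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_platform_profile(profile: pd.DataFrame, ax=None, title: str | None = None):
    """Plot log-scale mean ± SEM metabolite levels per platform.

    ``profile`` is the output of :func:`ringtrial.accuracy.platform_profile`
    (columns platform, metabolite, log_mean, log_sem).  Each platform's
    metabolites are spread along x in name order; error bars are the SEM of
    the natural-log values, so vertical distance is relative difference.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    prof = profile[profile["assessable"]].sort_values(["platform", "metabolite"])
    for platform, sub in prof.groupby("platform"):
        x = np.arange(len(sub))
        ax.errorbar(x, sub["log_mean"], yerr=sub["log_sem"], fmt="o", ms=3,
                    capsize=2, label=platform, alpha=0.8)
    ax.set_xlabel("metabolite (ordered by name)")
    ax.set_ylabel("ln concentration (µM)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
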