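"""Accuracy-profile plot: per-level tolerance limits vs the acceptance band."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .accuracy_profile import AccuracyProfile


def plot_accuracy_profile(profile: AccuracyProfile, ax: plt.Axes | None = None):
    """Bias, tolerance limits and acceptance lines against concentration."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    c = profile.levels
    ax.plot(c, [iv.bias_pct for iv in profile.intervals], "r-o", label="relative bias")
    ax.plot(c, [iv.l_pct for iv in profile.intervals], "b--", label="tolerance limits")
    ax.plot(c, [iv.u_pct for iv in profile.intervals], "b--")
    ax.axhline(profile.acceptance_pct, color="red", ls=":", label="acceptance limits")
    ax.axhline(-profile.acceptance_pct, color="red", ls=":")
    for q, name in ((profile.lloq, "LLOQ"), (profile.uloq, "ULOQ")):
        if q is not None:
            ax.axvline(q, color="grey", lw=0.8)
            ax.annotate(name, (q, ax.get_ylim()[1] * 0.9), fontsize=8, ha="center")
    ax.set_xlabel("concentration (mg/100 mL)")
    ax.set_ylabel("relative deviation (%)")
    ax.legend(fontsize=8)
    return ax.figure
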