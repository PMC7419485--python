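"""Minimal IRF curve plotting (requires matplotlib, ``plot`` extra)."""

from __future__ import annotations

import numpy as np

from .irf import IRFResult


def plot_irf(result: IRFResult, ax=None):
    """Plot one impulse/response curve with its confidence band.

    Solid line: mean response per month ahead; dashed lines: bootstrap
    band; dotted line: zero change.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    h = np.arange(result.horizon + 1)
    ax.plot(h, result.mean, "k-", lw=1.5)
    if result.lower is not None:
        ax.plot(h, result.lower, "k--", lw=1)
        ax.plot(h, result.upper, "k--", lw=1)
    ax.axhline(0.0, ls=":", color="k", lw=0.8)
    ax.set_xlabel("months ahead")
    ax.set_ylabel(f"response of {result.response}")
    ax.set_title(f"impulse: {result.impulse}")
    return ax
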