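"""Convergence-trace plotting helper (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .ga import ConvergenceTrace


def plot_traces(traces: Sequence[ConvergenceTrace], path: str | Path,
                normalize: bool = True) -> None:
    """Plot best fitness per generation (± population SD band) for each run.

    With ``normalize`` the fitness axis is min-max scaled to [0, 1] across
    all traces; raw values are never modified, scaling is presentation-only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    best = [np.asarray(t.best) for t in traces]
    sd = [np.asarray(t.sd) for t in traces]
    if normalize:
        lo = min(b.min() for b in best)
        hi = max(b.max() for b in best)
        span = hi - lo if hi > lo else 1.0
        best = [(b - lo) / span for b in best]
        sd = [s / span for s in sd]
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, (b, s) in enumerate(zip(best, sd)):
        gens = np.arange(1, len(b) + 1)
        ax.plot(gens, b, lw=1, label=f"run {i + 1}")
        ax.fill_between(gens, b - s, b + s, alpha=0.15)
    ax.set_xlabel("generation")
    ax.set_ylabel("best fitness" + (" (normalized)" if normalize else ""))
    if len(traces) <= 8:
        ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
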