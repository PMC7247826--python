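"""Stacked I_IN / V_MEM / V_OUT rendering of a trace."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .trace import Trace

__all__ = ["plot_trace"]


def plot_trace(trace: Trace, path=None, title: str = ""):
    """Three stacked panels: input current, membrane voltage, output voltage."""
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 6))
    t_ms = trace.t * 1e3
    axes[0].plot(t_ms, trace.u * 1e6, color="tab:red", lw=1.0)
    axes[0].set_ylabel(r"$I_{IN}$ [$\mu$A]")
    axes[1].plot(t_ms, trace.v_mem, color="tab:green", lw=1.0)
    axes[1].set_ylabel(r"$V_{MEM}$ [V]")
    axes[2].plot(t_ms, trace.v_out, color="tab:blue", lw=1.0)
    axes[2].set_ylabel(r"$V_{OUT}$ [V]")
    axes[2].set_xlabel("time [ms]")
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
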