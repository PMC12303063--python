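"""Optional plots: Kaplan-Meier risk-group curves and decision curves.

Matplotlib is imported lazily so headless/metrics-only runs never touch it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_km", "plot_decision_curve"]


def _step_xy(times: np.ndarray, survival: np.ndarray):
    x = np.concatenate([[0.0], np.repeat(times, 2)])
    y = np.concatenate([[1.0, 1.0], np.repeat(survival, 2)[:-1]])
    return x, y


def plot_km(curves: dict, path=None, title: str = "Overall survival"):
    """curves: group label -> SurvivalCurve; saves to `path` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.step(*_step_xy(curve.times, curve.survival), where="post", label=label)
    ax.set_xlabel("years")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_decision_curve(curve, path=None, title: str = "Decision curve"):
    """curve: a NetBenefitCurve; saves to `path` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.thresholds, curve.model, label="model policy")
    ax.plot(curve.thresholds, curve.treat_all, "--", label="treat all")
    ax.plot(curve.thresholds, curve.treat_none, ":", label="treat none")
    ax.set_xlabel("threshold probability $p_t$")
    ax.set_ylabel("net benefit")
    ax.set_title(f"{title} (w={curve.harm_weight})")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
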