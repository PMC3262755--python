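"""Control-chart plotting for surveillance trajectories."""

from __future__ import annotations

from .sprt import SprtTrajectory


def plot_trajectory(trajectory: SprtTrajectory, ax=None):
    """Draw one hospital-period chart: cumulative statistic and boundaries.

    Crossing steps are marked; the upper (alert) and lower (accept-null)
    boundaries are drawn as horizontal lines.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    steps = trajectory.steps
    xs = [s.index for s in steps]
    ys = [s.cumulative for s in steps]
    ax.step(xs, ys, where="post", lw=1.2, label="cumulative log-likelihood ratio")
    ax.axhline(trajectory.boundaries.h1, color="crimson", ls="--", lw=1, label="h1 (alert)")
    ax.axhline(trajectory.boundaries.h0, color="seagreen", ls="--", lw=1, label="h0 (accept null)")
    ax.axhline(0.0, color="0.6", lw=0.5)
    for idx, boundary in trajectory.crossings:
        ax.plot(idx, steps[idx].cumulative, "o",
                color="crimson" if boundary == "h1" else "seagreen", ms=5)
    ax.set_xlabel("case sequence within period")
    ax.set_ylabel("T cumulative")
    ax.set_title(f"{trajectory.hospital_id} {trajectory.period_label}"
                 + ("  [ALERT]" if trajectory.alerted else ""))
    ax.legend(loc="best", fontsize=8)
    return ax
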