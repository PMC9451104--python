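"""A minimal trajectory figure: populations, capacities and coefficients."""

from __future__ import annotations

from .simulate import Trajectory

__all__ = ["plot_trajectory"]


def plot_trajectory(trajectory: Trajectory, path=None):
    """Two stacked panels: population levels (with carrying capacities) and
    coevolution coefficients over time. Returns the matplotlib figure;
    saves to ``path`` when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = [s.time for s in trajectory.states]
    fig, (ax_pop, ax_coevo) = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
    ax_pop.plot(t, trajectory.humans, label="humans", color="tab:cyan")
    ax_pop.plot(t, trajectory.plants, label="plants", color="tab:pink")
    ax_pop.plot(
        t, trajectory.carrying_capacity_humans, ":", color="tab:cyan", alpha=0.6,
        label="K humans",
    )
    ax_pop.plot(
        t, trajectory.carrying_capacity_plants, ":", color="tab:pink", alpha=0.6,
        label="K plants",
    )
    ax_pop.set_ylabel("population / capacity")
    ax_pop.legend(loc="best", fontsize=8)
    ax_coevo.plot(t, trajectory.coevolution_coefficient_humans, color="tab:cyan", label="humans")
    ax_coevo.plot(t, trajectory.coevolution_coefficient_plants, color="tab:pink", label="plants")
    ax_coevo.axhline(trajectory.params.coevolution_threshold, ls="--", color="grey", lw=0.8)
    ax_coevo.set_ylim(-1.05, 1.05)
    ax_coevo.set_ylabel("coevolution coefficient")
    ax_coevo.set_xlabel("time step")
    ax_coevo.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
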