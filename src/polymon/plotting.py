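"""Simple trajectory plots: predicted composition vs reference points."""

from __future__ import annotations

__all__ = ["plot_prediction_series"]


def plot_prediction_series(series, run=None, path=None, title: str | None = None):
    """Plot the predicted per-form time course of a run.

    Parameters
    ----------
    series : PredictionSeries
        Output of :func:`polymon.calibration.predict_run` (the clipped,
        closure-consistent composition is drawn).
    run : ProcessRun, optional
        When given, the run's reference mass fractions are overlaid as points.
    path : str or Path, optional
        Save the figure instead of returning it interactively.
    """
    import matplotlib
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for form in series.clipped.columns:
        ax.plot(series.times, series.clipped[form], label=f"{form} (predicted)")
    if run is not None:
        wide = run.reference_wide()
        for form in wide.columns:
            ax.plot(wide.index, wide[form], "o", ms=4, mfc="none",
                    label=f"{form} (reference)")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("mass fraction")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(fontsize=7, ncol=2)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
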