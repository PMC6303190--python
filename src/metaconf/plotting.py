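"""Plot helpers for the posterior-predictive confidence table."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_confidence_cells"]

_CONDITION_ORDER = ["task1", "task2_low", "task2_high"]
_CONDITION_LABELS = ["confidence task", "low PDE", "high PDE"]


def plot_confidence_cells(table: pd.DataFrame, ax=None):
    """Plot group-average confidence by condition, split by accuracy and
    group (the decile-split posterior-predictive figure).

    ``table`` is the output of :func:`metaconf.fitting.posterior_predictive`:
    one row per group x condition x accuracy with mean confidence and a 95%
    CI.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    styles = {"correct": dict(color="tab:green"), "incorrect": dict(color="tab:red")}
    dashes = {"moderate": "-", "radical": "--"}
    x = range(len(_CONDITION_ORDER))
    for (group, acc), sub in table.groupby(["group", "accuracy"]):
        sub = sub.set_index("condition").reindex(_CONDITION_ORDER)
        ax.errorbar(
            x,
            sub.mean_confidence,
            yerr=[sub.mean_confidence - sub.ci_low, sub.ci_high - sub.mean_confidence],
            linestyle=dashes.get(group, "-"),
            label=f"{group}, {acc}",
            capsize=3,
            **styles.get(acc, {}),
        )
    ax.set_xticks(list(x), _CONDITION_LABELS)
    ax.set_ylabel("confidence")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax
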