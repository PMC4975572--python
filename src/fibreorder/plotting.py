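"""Minimal visualization: a per-group strip chart of orderness scores."""

from __future__ import annotations

import numpy as np

from .score import OrdernessResult, summarize_groups


def strip_chart(results: list[OrdernessResult], ax=None):
    """Strip chart of per-fibre g (percent) by group, with group mean ± SE bars.

    Returns the matplotlib Axes.  Import of matplotlib is deferred so the
    numerical pipeline has no hard plotting dependency at import time.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + 1.1 * len({r.group for r in results}), 3.2))
    summaries = summarize_groups(results)
    rng = np.random.default_rng(0)  # jitter is cosmetic only
    for x, s in enumerate(summaries):
        ys = [r.g_percent for r in results if r.group == s.group]
        xs = x + rng.uniform(-0.12, 0.12, len(ys))
        ax.plot(xs, ys, "o", ms=4, alpha=0.6)
        ax.errorbar([x], [s.mean_g_percent], yerr=[s.se_g_percent], fmt="_", ms=18,
                    color="black", capsize=4, lw=1.5, zorder=3)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(range(len(summaries)), [s.group for s in summaries])
    ax.set_ylabel("orderness g (%)")
    return ax
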