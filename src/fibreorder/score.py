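"""The orderness score and group-level comparison.

For one fibre, the score

    g = (ME − MR) / (MO − MR)

normalizes the experimental mean nearest-neighbour distance ME between the
random reference MR (g = 0, complete spatial randomness) and the optimal
reference MO (g = 1, maximally spread nuclei).  g is reported unclipped: values
below 0 indicate patterns more clustered than random, and values slightly
above 1 can occur because MO is a heuristic lower bound on the true optimum;
both are flagged.

Groups of fibres are compared on g (in percent) with a one-way ANOVA followed
by Bonferroni-adjusted pairwise comparisons, treating fibres as replicates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from ._rng import derive_seed
from .errors import (
    DegenerateNormalizationError,
    DuplicatePointsWarning,
    InsufficientDataError,
    UndefinedStatisticError,
)
from .geometry import fit_cylinder, pairwise_surface_distances, project_to_surface
from .spatial import mean_nn_distance, optimal_mean_nn, simulate_random_mean

log = logging.getLogger(__name__)

__all__ = [
    "OrdernessResult",
    "GroupSummary",
    "AnovaReport",
    "orderness_score",
    "score_fibre",
    "summarize_groups",
    "compare_groups",
]


@dataclass(frozen=True)
class OrdernessResult:
    """Per-fibre orderness outcome with the quantities that produced it."""

    fibre_id: str
    group: str
    n_nuclei: int
    radius_um: float
    length_um: float
    me: float
    mr: float
    mr_se: float
    mo: float
    g: float
    g_percent: float
    g_se: float
    flags: tuple[str, ...]
    config_digest: str


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n_fibres: int
    mean_g_percent: float
    se_g_percent: float


@dataclass(frozen=True)
class AnovaReport:
    F: float
    df_between: int
    df_within: int
    p: float
    pairwise_bonferroni_p: dict[tuple[str, str], float]


def orderness_score(me: float, mr: float, mo: float, *, rel_tol: float = 1e-6) -> float:
    """g = (ME − MR)/(MO − MR); unclipped.

    Raises :class:`DegenerateNormalizationError` when MO − MR is below
    ``rel_tol · max(MR, 1)`` — tiny n or degenerate geometry make the
    normalization meaningless.
    """
    denom = mo - mr
    if denom <= rel_tol * max(abs(mr), 1.0):
        raise DegenerateNormalizationError(
            f"MO ({mo:.4g}) does not exceed MR ({mr:.4g}); score undefined"
        )
    return (me - mr) / denom


def _min_separation_filter(points: np.ndarray, radius: float, min_sep: float, metric) -> np.ndarray:
    """Greedily drop points closer than ``min_sep`` (surface metric) to a kept point."""
    dist = pairwise_surface_distances(points, radius, metric=metric)
    keep: list[int] = []
    for i in range(points.shape[0]):
        if all(dist[i, j] >= min_sep for j in keep):
            keep.append(i)
    return points[keep]


def score_fibre(fibre, config) -> OrdernessResult:
    """Run the full per-fibre pipeline: fit → project → ME → MR → MO → g.

    ``fibre`` is a :class:`~fibreorder.synthetic.FibreRecord` (or anything with
    ``fibre_id``, ``group`` and an ``(n, 3)`` ``nuclei`` array); ``config`` a
    :class:`~fibreorder.io.RunConfig`.  Sub-seeds for the Monte-Carlo null and
    the optimizer are derived from the master seed and the fibre id, so the
    result does not depend on batch order.
    """
    flags: list[str] = []
    cyl = fit_cylinder(fibre.nuclei)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", DuplicatePointsWarning)
        pts = project_to_surface(fibre.nuclei, cyl)
        if config.min_separation is not None:
            before = pts.shape[0]
            pts = _min_separation_filter(pts, cyl.radius, config.min_separation, config.metric)
            if pts.shape[0] < before:
                flags.append("min_separation_filtered")
        if pts.shape[0] < 2:
            raise InsufficientDataError("fewer than 2 nuclei after filtering")
        me = mean_nn_distance(pts, cyl.radius, metric=config.metric)
        if any(issubclass(w.category, DuplicatePointsWarning) for w in caught):
            flags.append("duplicate_points")

    n = pts.shape[0]
    mr_seed = derive_seed(config.master_seed, fibre.fibre_id, "random_null")
    mo_seed = derive_seed(config.master_seed, fibre.fibre_id, "optimal")
    null = simulate_random_mean(n, cyl, reps=config.mr_reps, seed=mr_seed, metric=config.metric)
    opt = optimal_mean_nn(
        n,
        cyl,
        restarts=config.mo_restarts,
        iterations=config.mo_iterations,
        seed=mo_seed,
        metric=config.metric,
    )
    g = orderness_score(me.mean_nn, null.mr_mean, opt.mo_mean)
    # first-order propagation of the Monte-Carlo error on MR into g
    g_se = null.mr_mc_se * abs(opt.mo_mean - me.mean_nn) / (opt.mo_mean - null.mr_mean) ** 2
    if config.clip_g:
        g = float(np.clip(g, 0.0, 1.0))
    elif g < 0.0:
        flags.append("g_below_0")
    elif g > 1.0:
        flags.append("g_above_1")
    log.info(
        "fibre %s: n=%d ME=%.3f MR=%.3f MO=%.3f g=%.3f", fibre.fibre_id, n, me.mean_nn,
        null.mr_mean, opt.mo_mean, g,
    )
    return OrdernessResult(
        fibre_id=str(fibre.fibre_id),
        group=str(fibre.group),
        n_nuclei=n,
        radius_um=cyl.radius,
        length_um=cyl.length,
        me=me.mean_nn,
        mr=null.mr_mean,
        mr_se=null.mr_mc_se,
        mo=opt.mo_mean,
        g=float(g),
        g_percent=100.0 * float(g),
        g_se=float(g_se),
        flags=tuple(flags),
        config_digest=config.digest(),
    )


def summarize_groups(results: list[OrdernessResult]) -> list[GroupSummary]:
    """Per-group mean ± SE of g (percent), groups in label order."""
    if not results:
        raise InsufficientDataError("no results to summarize")
    by_group: dict[str, list[float]] = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r.g_percent)
    summaries = []
    for lab in sorted(by_group):
        vals = np.asarray(by_group[lab])
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        summaries.append(
            GroupSummary(group=lab, n_fibres=len(vals), mean_g_percent=float(vals.mean()),
                         se_g_percent=se)
        )
    return summaries


def compare_groups(
    results: list[OrdernessResult],
) -> tuple[list[GroupSummary], AnovaReport | None]:
    """Per-group mean ± SE of g (percent) and one-way ANOVA with Bonferroni
    pairwise follow-ups.

    Pairwise comparisons use t statistics on the pooled within-group mean
    square (the classic Bonferroni multiple-comparison test); adjusted p-values
    are min(1, raw · n_comparisons).  With a single group only the summary is
    returned (no ANOVA).
    """
    summaries = summarize_groups(results)
    labels = [s.group for s in summaries]
    if len(labels) < 2:
        return summaries, None

    by_group: dict[str, list[float]] = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r.g_percent)
    samples = [np.asarray(by_group[lab]) for lab in labels]
    if any(len(s) < 2 for s in samples):
        raise InsufficientDataError("every group needs >= 2 fibres for ANOVA")
    df_within = sum(len(s) - 1 for s in samples)
    ssw = sum(float(((s - s.mean()) ** 2).sum()) for s in samples)
    if ssw == 0.0:
        raise UndefinedStatisticError("zero within-group variance everywhere; F undefined")
    F, p = stats.f_oneway(*samples)
    msw = ssw / df_within
    pairs: dict[tuple[str, str], float] = {}
    n_comp = len(labels) * (len(labels) - 1) // 2
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = samples[i], samples[j]
            t = (a.mean() - b.mean()) / np.sqrt(msw * (1 / len(a) + 1 / len(b)))
            raw = 2.0 * stats.t.sf(abs(t), df_within)
            pairs[(labels[i], labels[j])] = min(1.0, float(raw) * n_comp)
    report = AnovaReport(
        F=float(F),
        df_between=len(labels) - 1,
        df_within=df_within,
        p=float(p),
        pairwise_bonferroni_p=pairs,
    )
    return summaries, report


def clip_to_unit(result: OrdernessResult) -> OrdernessResult:
    """Return a copy with g clipped to [0, 1] (convenience; not the default)."""
    g = float(np.clip(result.g, 0.0, 1.0))
    return replace(result, g=g, g_percent=100.0 * g)
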