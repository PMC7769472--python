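"""Statistical process control for interpretive rates.

Funnel-plot control limits around the group median rate, volume
normalization of PIRs onto a common (maximum-volume) scale, outlier
classification at nested confidence levels, and chart rendering.

The control limits use the normal approximation to the binomial at the
GMIR: for a rater with denominator n, the null standard deviation is
sd = sqrt(GMIR·(1−GMIR)/n) and the two-sided level-``alpha`` limits are
GMIR ± z(1−alpha/2)·sd, truncated into [0, 1].  An exact-binomial test is
available behind a flag for small denominators.

Normalization re-expresses each rater's rate at the cohort's maximum
volume while preserving its standard-deviation distance to the GMIR:

    norm = GMIR + (pir − GMIR)·sqrt(n_i / n_max)

so that all raters share straight control lines computed with sd at
n_max.  It shrinks deviations of low-volume raters (never changing their
sign or their z-score) and maps a zero rate to GMIR·(1 − sqrt(n_i/n_max)),
which is positive — a zero rate at low volume is weaker evidence of a
truly low rate than a zero at high volume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .rates import RateTable

logger = logging.getLogger(__name__)

#: Nested two-sided confidence levels used on the control charts.
DEFAULT_LEVELS = (0.05, 0.001, 1e-6, 1e-12)


@dataclass
class FunnelAssessment:
    """One rater's position relative to the funnel on one score level."""

    rater_id: str
    axis: str
    score_level: int
    pir: float
    n_i: int
    gmir: float
    sd_i: float
    z: float
    norm_pir: float
    outlier_level: float | None  # most extreme alpha breached, None if inside


def funnel_limits(gmir: float, n: int, alpha: float) -> tuple[float, float]:
    """Two-sided control limits for a rate at denominator ``n``.

    Limits are ``gmir ± z(1−alpha/2)·sqrt(gmir(1−gmir)/n)``, truncated into
    [0, 1].  ``gmir`` must be strictly inside (0, 1); a degenerate centre
    line has zero binomial variance and no meaningful limits.
    """
    if not 0.0 < gmir < 1.0:
        raise ValueError(f"gmir={gmir} must be strictly between 0 and 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    sd = math.sqrt(gmir * (1.0 - gmir) / n)
    half = stats.norm.isf(alpha / 2.0) * sd
    return max(0.0, gmir - half), min(1.0, gmir + half)


def normalize_pir(pir: float, n_i: int, gmir: float, n_max: int) -> float:
    """Re-express ``pir`` at the maximum volume, preserving its z-distance
    to the GMIR (see module docstring for the closed form)."""
    if n_i > n_max:
        raise ValueError(f"n_i={n_i} exceeds n_max={n_max}")
    if n_i < 1:
        raise ValueError("n_i must be >= 1")
    if not 0.0 < gmir < 1.0:
        raise ValueError(f"gmir={gmir} must be strictly between 0 and 1")
    return gmir + (pir - gmir) * math.sqrt(n_i / n_max)


def _exact_binomial_breach(count: int, n: int, gmir: float, alpha: float) -> bool:
    """Two-sided exact test: either binomial tail at ``count`` has
    probability <= alpha/2 under rate ``gmir``."""
    lo = stats.binom.cdf(count, n, gmir)
    hi = stats.binom.sf(count - 1, n, gmir)
    return min(lo, hi) <= alpha / 2.0


def classify_outliers(
    table: RateTable,
    levels: Sequence[float] = DEFAULT_LEVELS,
    exact: bool = False,
) -> list[FunnelAssessment]:
    """Assign each rater the most extreme confidence level it breaches.

    ``levels`` must be strictly decreasing alphas (e.g. 0.05, 0.001, ...).
    ``outlier_level`` is the smallest breached alpha, or None when the
    rater sits inside the widest funnel.  Counts at a given level are
    conventionally reported cumulatively (a p<0.001 breach also counts at
    p<0.05); see :func:`outlier_counts`.  With ``exact=True`` the breach
    test uses binomial tail probabilities instead of the normal
    approximation.
    """
    levels = tuple(levels)
    if any(b >= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly decreasing")
    gmir = table.gmir
    if not 0.0 < gmir < 1.0:
        raise ValueError(
            f"GMIR={gmir} for {table.axis}{table.score_level} is degenerate; "
            "funnel analysis undefined"
        )
    n_max = table.n_max
    out: list[FunnelAssessment] = []
    for rid, pir, n_i in zip(table.rater_ids, table.pir, table.n):
        n_i = int(n_i)
        sd_i = math.sqrt(gmir * (1.0 - gmir) / n_i)
        z = (pir - gmir) / sd_i
        breached: float | None = None
        for alpha in levels:  # widest to narrowest; keep the last breached
            if exact:
                hit = _exact_binomial_breach(round(pir * n_i), n_i, gmir, alpha)
            else:
                lo, hi = funnel_limits(gmir, n_i, alpha)
                hit = pir < lo or pir > hi
            if hit:
                breached = alpha
            else:
                break
        out.append(
            FunnelAssessment(
                rater_id=rid,
                axis=table.axis,
                score_level=table.score_level,
                pir=float(pir),
                n_i=n_i,
                gmir=gmir,
                sd_i=sd_i,
                z=float(z),
                norm_pir=normalize_pir(float(pir), n_i, gmir, n_max),
                outlier_level=breached,
            )
        )
    return out


def outlier_counts(
    assessments: Sequence[FunnelAssessment],
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> dict[float, int]:
    """Cumulative outlier counts per level: a rater breaching a narrow
    funnel is also counted at every wider one."""
    return {
        alpha: sum(
            1
            for a in assessments
            if a.outlier_level is not None and a.outlier_level <= alpha
        )
        for alpha in levels
    }


def render_control_chart(
    assessments: Sequence[FunnelAssessment],
    path: str | Path,
    levels: Sequence[float] = DEFAULT_LEVELS,
    seed: int | None = None,
    fmt: str | None = None,
):
    """Control chart: normalized PIRs vs randomly ordered raters.

    Centre line at the GMIR; straight control lines at each level computed
    with the maximum-volume standard deviation (valid for every point
    because normalization preserves z-distances).  Rater order on the
    x-axis is shuffled under ``seed`` — a presentation choice that also
    de-emphasises identity.  Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not assessments:
        raise ValueError("need at least one assessment")
    gmir = assessments[0].gmir
    n_max = max(a.n_i for a in assessments)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(assessments))

    fig, ax = plt.subplots(figsize=(6, 4))
    ys = [assessments[i].norm_pir for i in order]
    ax.scatter(range(1, len(ys) + 1), ys, color="red", zorder=3)
    ax.axhline(gmir, color="black", lw=1.5, label="GMIR")
    styles = {0: "--", 1: "-"}  # dashed 95%, solid 99.9%, dashed beyond
    for j, alpha in enumerate(sorted(levels, reverse=True)):
        lo, hi = funnel_limits(gmir, n_max, alpha)
        ls = styles.get(j, "--")
        ax.axhline(lo, color="blue", ls=ls, lw=0.8)
        ax.axhline(hi, color="blue", ls=ls, lw=0.8)
    a0 = assessments[0]
    ax.set_xlabel("pathologist (random order)")
    ax.set_ylabel("normalized PIR")
    ax.set_title(f"{a0.axis}{a0.score_level}")
    ax.set_xticks(range(1, len(ys) + 1))
    fig.savefig(str(path), format=fmt)
    plt.close(fig)
    return fig


def render_raw_rate_bars(
    tables: Sequence[RateTable],
    path: str | Path,
    seed: int | None = None,
    fmt: str | None = None,
):
    """Companion bar chart of raw PIRs for one axis (one group of stacked
    level bars per rater, same random rater order convention)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not tables:
        raise ValueError("need at least one rate table")
    axis = tables[0].axis
    rater_ids = tables[0].rater_ids
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rater_ids))

    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {1: "green", 2: "gold", 3: "red"}
    bottom = np.zeros(len(rater_ids))
    for t in sorted(tables, key=lambda t: t.score_level):
        vals = np.asarray(t.pir)[order]
        ax.bar(
            range(1, len(vals) + 1),
            vals,
            bottom=bottom,
            color=colors[t.score_level],
            label=f"{axis}{t.score_level}",
        )
        bottom += vals
    ax.set_xlabel("pathologist (random order)")
    ax.set_ylabel("raw PIR")
    ax.set_title(axis)
    ax.legend(fontsize=8)
    fig.savefig(str(path), format=fmt)
    plt.close(fig)
    return fig
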