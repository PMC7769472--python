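"""Interpretive-rate tables: per-rater PIRs and the group median (GMIR).

The PIR of rater *i* for score level *k* on an axis is the fraction of the
rater's scored cases on that axis assigned level *k*.  The GMIR for a level
is the median of the included raters' PIRs; it is the centre line of the
funnel and control charts and the null rate for outlier classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import AXES, SCORE_LEVELS, RaterProfile


@dataclass
class RateTable:
    """All included raters' PIRs for one axis and score level.

    Raters with a zero axis denominator are excluded before construction,
    so ``pir`` and ``n`` are aligned arrays over usable raters only.
    """

    axis: str
    score_level: int
    rater_ids: tuple[str, ...]
    pir: np.ndarray  # shape (R,), proportions in [0, 1]
    n: np.ndarray  # shape (R,), axis denominators

    @property
    def gmir(self) -> float:
        """Group median interpretive rate (even count: midpoint of the two
        central order statistics)."""
        return float(np.median(self.pir))

    @property
    def n_max(self) -> int:
        return int(self.n.max())

    def __len__(self) -> int:
        return len(self.rater_ids)


def rate_table(profiles: Sequence[RaterProfile], score_level: int) -> RateTable:
    """Build the PIR table for one score level from per-rater profiles.

    Degenerate profiles (no scored case on the axis) are dropped; at least
    two usable raters are required, since a group median of one rater is
    not a meaningful comparison centre.
    """
    if score_level not in SCORE_LEVELS:
        raise ValueError(f"score_level must be in {SCORE_LEVELS}")
    usable = [p for p in profiles if not p.degenerate]
    if len(usable) < 2:
        raise ValueError(
            f"need >=2 raters with a non-zero denominator, got {len(usable)}"
        )
    axes = {p.axis for p in usable}
    if len(axes) != 1:
        raise ValueError(f"profiles mix axes: {sorted(axes)}")
    k = score_level - 1
    return RateTable(
        axis=axes.pop(),
        score_level=score_level,
        rater_ids=tuple(p.rater_id for p in usable),
        pir=np.array([p.pir[k] for p in usable], dtype=float),
        n=np.array([p.n_axis for p in usable], dtype=int),
    )


def round_half_up(x: float, digits: int = 0) -> float:
    """Round half away from zero (the convention of printed clinical tables;
    numpy/python round half to even)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def median_pir_summary(tables: Sequence[RateTable]) -> pd.DataFrame:
    """Per score level: median PIR and the normalized PIR range, in percent.

    Expects the twelve tables TS1..TS3, NS1..NS3, MS1..MS3, G1..G3 (any
    subset is accepted).  Medians and range bounds are rounded half-up to
    integer percent for display; use the tables directly for full precision.
    The three level medians on an axis need not sum to exactly 100%: each
    is a median over raters, not a share of a common total.
    """
    from .spc import normalize_pir  # local import: spc depends on rates types

    order = {ax: i for i, ax in enumerate(AXES)}
    rows = []
    for t in sorted(tables, key=lambda t: (order[t.axis], t.score_level)):
        gmir, n_max = t.gmir, t.n_max
        if 0.0 < gmir < 1.0:
            normed = [
                normalize_pir(p, n_i, gmir, n_max)
                for p, n_i in zip(t.pir, t.n)
            ]
        else:  # normalization undefined at a degenerate centre line
            normed = list(t.pir)
        rows.append(
            {
                "axis": t.axis,
                "score_level": t.score_level,
                "parameter": f"{t.axis}{t.score_level}",
                "median_pir_pct": round_half_up(100 * gmir),
                "norm_low_pct": round_half_up(100 * min(normed)),
                "norm_high_pct": round_half_up(100 * max(normed)),
                "n_raters": len(t),
            }
        )
    return pd.DataFrame(rows)
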