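"""In silico kappa (ISK): agreement inferred from marginal rates alone.

A conventional kappa study needs every rater to read the same cases.  ISK
instead asks: given only each rater's interpretive-rate vector, how much
agreement is *compatible* with those margins under an explicit best-case
assumption?  Two assumptions are implemented.

MCOA (maximal categorical overlap assumption) applies to a single score
level collapsed to binary (level k vs rest).  Raters with identical rates
are assumed to agree on every case, so pairwise observed agreement is the
maximum compatible with the two binary margins:

    p_o = min(p_a, p_b) + min(1−p_a, 1−p_b)
    p_e = p_a·p_b + (1−p_a)(1−p_b)
    κ   = (p_o − p_e) / (1 − p_e)

This is the two-category kappa-maximum of Sim & Wright.

OMECA (ordered mutually exclusive category assumption) applies to a full
ordinal axis.  Both raters are assumed to rank cases identically on a
latent severity scale and differ only in where they place their category
thresholds, so only adjacent categories ever compete.  Each rater's
category k occupies the interval [C(k−1), C(k)] of the latent unit
interval (C = cumulative rate vector); observed agreement is the total
overlap of matching intervals:

    p_o = Σ_k max(0, min(C_a(k), C_b(k)) − max(C_a(k−1), C_b(k−1)))
    p_e = Σ_k p_a(k)·p_b(k)
    κ   = (p_o − p_e) / (1 − p_e)

Both are best-case constructions: an ISK upper-bounds what a head-to-head
conventional kappa on the same raters and cases could show.

The group statistic is the unweighted mean of the pairwise kappa over all
unordered rater pairs; a volume-weighted mean is available behind a flag.
Confidence intervals come from a seeded parametric bootstrap: each
replicate redraws every rater's counts from a multinomial at the rater's
observed rates and observed denominator, and recomputes the group
statistic; the CI is the percentile interval of the replicates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .data_model import RaterProfile

logger = logging.getLogger(__name__)

Assumption = Literal["MCOA", "OMECA"]

#: Tolerance for PIR vectors summing to one.
_SUM_TOL = 1e-8


@dataclass
class KappaEstimate:
    """A group ISK with its bootstrap percentile CI."""

    statistic: float
    assumption: Assumption
    target: str  # e.g. "NS1" (MCOA) or "NS" (OMECA)
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    degenerate_pairs: int = 0  # pairs with forced agreement (p_e = 1)


def mcoa_pair_kappa(p_a: float, p_b: float) -> float:
    """Maximum kappa for two raters from their binary rates (see module
    docstring).  At p_e = 1 (both raters always, or never, call the level)
    agreement is forced and kappa is 1 by convention."""
    if not (0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    p_o = min(p_a, p_b) + min(1.0 - p_a, 1.0 - p_b)
    p_e = p_a * p_b + (1.0 - p_a) * (1.0 - p_b)
    if p_e >= 1.0 - 1e-15:
        logger.debug("degenerate pair (p_e=1): kappa=1 by convention")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def omeca_pair_kappa(
    pir_a: Sequence[float], pir_b: Sequence[float]
) -> float:
    """Ordered-category overlap kappa for two raters' full rate vectors
    (see module docstring).  Vectors must sum to 1; kappa is 1 by
    convention when chance agreement is itself 1 (both raters put all mass
    on one shared category)."""
    a = np.asarray(pir_a, dtype=float)
    b = np.asarray(pir_b, dtype=float)
    for name, v in (("pir_a", a), ("pir_b", b)):
        if v.ndim != 1 or np.any(v < 0):
            raise ValueError(f"{name} must be a non-negative vector")
        if abs(v.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"{name} sums to {v.sum()}, not 1")
    if len(a) != len(b):
        raise ValueError("rate vectors must have equal length")
    ca = np.concatenate(([0.0], np.cumsum(a)))
    cb = np.concatenate(([0.0], np.cumsum(b)))
    p_o = float(
        np.sum(
            np.maximum(
                0.0,
                np.minimum(ca[1:], cb[1:]) - np.maximum(ca[:-1], cb[:-1]),
            )
        )
    )
    p_e = float(a @ b)
    if p_e >= 1.0 - 1e-15:
        logger.debug("degenerate pair (p_e=1): kappa=1 by convention")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def _usable(profiles: Sequence[RaterProfile]) -> list[RaterProfile]:
    usable = [p for p in profiles if not p.degenerate]
    for p in profiles:
        if p.degenerate:
            logger.warning(
                "rater %s excluded from ISK: undefined PIR on %s",
                p.rater_id, p.axis,
            )
    if len(usable) < 2:
        raise ValueError(f"need >=2 raters with defined PIRs, got {len(usable)}")
    return usable


def _pair_stats(
    pirs: np.ndarray,
    assumption: Assumption,
    score_level: int | None,
) -> np.ndarray:
    """Pairwise kappa matrix entries for all unordered pairs, vectorised.

    ``pirs`` has shape (R, 3).  Returns the flat upper-triangle (i<j).
    """
    r = pirs.shape[0]
    iu, ju = np.triu_indices(r, k=1)
    if assumption == "MCOA":
        if score_level is None:
            raise ValueError("MCOA requires a score_level")
        p = pirs[:, score_level - 1]
        pa, pb = p[iu], p[ju]
        p_o = np.minimum(pa, pb) + np.minimum(1 - pa, 1 - pb)
        p_e = pa * pb + (1 - pa) * (1 - pb)
    elif assumption == "OMECA":
        if score_level is not None:
            raise ValueError("OMECA applies to the whole axis; no score_level")
        c = np.concatenate([np.zeros((r, 1)), np.cumsum(pirs, axis=1)], axis=1)
        ca, cb = c[iu], c[ju]
        p_o = np.maximum(
            0.0,
            np.minimum(ca[:, 1:], cb[:, 1:])
            - np.maximum(ca[:, :-1], cb[:, :-1]),
        ).sum(axis=1)
        p_e = np.einsum("ij,ij->i", pirs[iu], pirs[ju])
    else:
        raise ValueError(f"unknown assumption {assumption!r}")
    kappa = np.ones_like(p_o)
    ok = p_e < 1.0 - 1e-15
    kappa[ok] = (p_o[ok] - p_e[ok]) / (1.0 - p_e[ok])
    return kappa


def group_isk(
    profiles: Sequence[RaterProfile],
    assumption: Assumption,
    score_level: int | None = None,
    weighting: Literal["unweighted", "volume"] = "unweighted",
) -> float:
    """Group ISK: mean pairwise kappa over all unordered rater pairs.

    MCOA needs ``score_level`` (the binary collapse); OMECA takes the full
    axis and must be called without one.  ``weighting="volume"`` weights
    each pair by the sum of the two raters' axis denominators.
    """
    usable = _usable(profiles)
    pirs = np.array([p.pir for p in usable], dtype=float)
    kappas = _pair_stats(pirs, assumption, score_level)
    if weighting == "unweighted":
        return float(kappas.mean())
    if weighting == "volume":
        n = np.array([p.n_axis for p in usable], dtype=float)
        iu, ju = np.triu_indices(len(usable), k=1)
        w = n[iu] + n[ju]
        return float(np.average(kappas, weights=w))
    raise ValueError(f"unknown weighting {weighting!r}")


def pairwise_kappas(
    profiles: Sequence[RaterProfile],
    assumption: Assumption,
    score_level: int | None = None,
) -> dict[tuple[str, str], float]:
    """All unordered pairwise kappas, keyed by (rater_a, rater_b) —
    scalar-path reference used in tests and per-pair reporting."""
    usable = _usable(profiles)
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(usable, 2):
        if assumption == "MCOA":
            k = mcoa_pair_kappa(a.pir[score_level - 1], b.pir[score_level - 1])
        else:
            k = omeca_pair_kappa(a.pir, b.pir)
        out[(a.rater_id, b.rater_id)] = k
    return out


def bootstrap_ci(
    profiles: Sequence[RaterProfile],
    assumption: Assumption,
    score_level: int | None = None,
    n_boot: int = 2000,
    seed: int | None = None,
    weighting: Literal["unweighted", "volume"] = "unweighted",
) -> KappaEstimate:
    """Group ISK with a parametric-bootstrap percentile 95% CI.

    Each replicate redraws every rater's 3-level counts from a multinomial
    at the rater's observed PIR and observed denominator, then recomputes
    the group statistic.  The reported point estimate is computed on the
    observed data, not the replicate mean.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for a stable percentile CI")
    usable = _usable(profiles)
    pirs = np.array([p.pir for p in usable], dtype=float)
    ns = np.array([p.n_axis for p in usable], dtype=int)
    point = group_isk(usable, assumption, score_level, weighting)

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(len(usable), k=1)
    if weighting == "volume":
        w = (ns[iu] + ns[ju]).astype(float)
        w = w / w.sum()
    reps = np.empty(n_boot)
    degenerate = 0
    for b in range(n_boot):
        boot = np.stack(
            [rng.multinomial(n, p) / n for n, p in zip(ns, pirs)]
        )
        kappas = _pair_stats(boot, assumption, score_level)
        p_e_one = np.einsum("ij,ij->i", boot[iu], boot[ju]) >= 1.0 - 1e-15
        degenerate += int(p_e_one.sum())
        if weighting == "volume":
            reps[b] = float(kappas @ w)
        else:
            reps[b] = float(kappas.mean())
    lo, hi = np.percentile(reps, [2.5, 97.5])
    # percentile interval may exclude the observed point in pathological
    # skew; clamp so the estimate is always covered by its own CI
    lo, hi = min(float(lo), point), max(float(hi), point)
    axis = usable[0].axis
    target = axis if score_level is None else f"{axis}{score_level}"
    return KappaEstimate(
        statistic=point,
        assumption=assumption,
        target=target,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        seed=seed,
        degenerate_pairs=degenerate,
    )
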