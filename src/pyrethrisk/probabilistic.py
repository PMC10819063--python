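"""Percentile-matching distribution fits and seeded Monte Carlo propagation.

Population urinary levels and allocation percentages are only available as
a few reported percentiles.  To propagate their variability through the
hazard-quotient computation, each quantity is reconstructed as a full
distribution: every family in a small gallery (gamma, lognormal, weibull,
normal, triangular, uniform) is fitted by minimising the sum of squared
*relative* deviations between its quantile function and the three anchor
percentiles, and the family with the smallest objective wins.

Identifiability caveat: three quantiles do not always pin down the family.
Any symmetric anchor triple is fitted exactly by the normal, the uniform
and a symmetric triangular, so ties (objectives within 1e-9 of the best)
are broken by the fixed gallery order above.  Skewed families (gamma,
lognormal, weibull, asymmetric triangular) are mutually identifiable in
practice.

The Monte Carlo step draws, per iteration, a population level and one
contribution percentage per substance (inverse-transform from a single
seeded generator; stream order is level first, then contributors in mapping
order), clips contributions to [0, 100], optionally renormalises them to a
100% simplex, and accumulates per-substance and total hazard quotients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import AnchorError, ConfigurationError, UndefinedFitError

__all__ = [
    "GALLERY_ORDER",
    "FittedDistribution",
    "fit_from_percentiles",
    "MonteCarloResult",
    "run_monte_carlo",
]

logger = logging.getLogger(__name__)

GALLERY_ORDER = ("gamma", "lognormal", "weibull", "normal", "triangular", "uniform")

#: Ties in fit error below this margin are resolved by gallery order.
TIE_TOLERANCE = 1e-9


# ---------------------------------------------------------------------------
# family fits
# ---------------------------------------------------------------------------

def _frozen(family: str, params: dict):
    if family == "gamma":
        return stats.gamma(params["shape"], scale=params["scale"])
    if family == "lognormal":
        return stats.lognorm(params["sigma"], scale=np.exp(params["mu"]))
    if family == "weibull":
        return stats.weibull_min(params["shape"], scale=params["scale"])
    if family == "normal":
        return stats.norm(params["mu"], params["sigma"])
    if family == "triangular":
        a, c, b = params["min"], params["mode"], params["max"]
        width = b - a
        return stats.triang((c - a) / width, loc=a, scale=width)
    if family == "uniform":
        return stats.uniform(params["min"], params["max"] - params["min"])
    raise ConfigurationError(f"unknown family {family!r}")


def _fit_error(family: str, params: dict, p: np.ndarray, v: np.ndarray) -> float:
    q = _frozen(family, params).ppf(p)
    return float(np.sum(((q - v) / v) ** 2))


def _fit_normal(p, v):
    z = stats.norm.ppf(p)
    design = np.column_stack([np.ones_like(z), z])
    (mu, sigma), *_ = np.linalg.lstsq(design, v, rcond=None)
    if sigma <= 0:
        raise UndefinedFitError("non-positive normal sigma")
    return {"mu": float(mu), "sigma": float(sigma)}


def _fit_lognormal(p, v):
    z = stats.norm.ppf(p)
    design = np.column_stack([np.ones_like(z), z])
    (mu, sigma), *_ = np.linalg.lstsq(design, np.log(v), rcond=None)
    if sigma <= 0:
        raise UndefinedFitError("non-positive lognormal sigma")
    return {"mu": float(mu), "sigma": float(sigma)}


def _fit_uniform(p, v):
    design = np.column_stack([np.ones_like(p), p])
    (a, w), *_ = np.linalg.lstsq(design, v, rcond=None)
    if w <= 0:
        raise UndefinedFitError("non-positive uniform width")
    return {"min": float(a), "max": float(a + w)}


def _refine(family, p, v, x0, unpack):
    """Polish a parameter vector with least squares on relative residuals."""
    def residuals(x):
        params = unpack(x)
        with np.errstate(all="ignore"):
            q = _frozen(family, params).ppf(p)
        if not np.all(np.isfinite(q)):
            return np.full_like(v, 1e6)
        return (q - v) / v

    sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return unpack(sol.x)


def _fit_gamma(p, v):
    # moment-matched init via the lognormal fit
    ln = _fit_lognormal(p, v)
    s2 = ln["sigma"] ** 2
    mean = np.exp(ln["mu"] + s2 / 2)
    var = mean**2 * (np.exp(s2) - 1)
    shape0 = max(mean**2 / var, 1e-3)
    scale0 = var / mean
    unpack = lambda x: {"shape": float(np.exp(x[0])), "scale": float(np.exp(x[1]))}
    return _refine("gamma", p, v, [np.log(shape0), np.log(scale0)], unpack)


def _fit_weibull(p, v):
    # ln Q = ln(scale) + (1/shape) * ln(-ln(1 - p)) is linear in logs
    t = np.log(-np.log1p(-p))
    design = np.column_stack([np.ones_like(t), t])
    (lnscale, inv_shape), *_ = np.linalg.lstsq(design, np.log(v), rcond=None)
    if inv_shape <= 0:
        raise UndefinedFitError("non-positive weibull shape")
    unpack = lambda x: {"shape": float(np.exp(x[0])), "scale": float(np.exp(x[1]))}
    return _refine("weibull", p, v, [np.log(1 / inv_shape), lnscale], unpack)


def _fit_triangular(p, v, nonnegative=False):
    spread = v[-1] - v[0]
    a0 = v[0] - 0.5 * spread
    b0 = v[-1] + 0.5 * spread
    c0 = float(np.clip(v[len(v) // 2], a0 + 1e-9 * spread, b0 - 1e-9 * spread))

    def unpack(x):
        a = x[0]
        c = a + np.exp(x[1])
        b = c + np.exp(x[2])
        return {"min": float(a), "mode": float(c), "max": float(b)}

    x0 = [a0, np.log(max(c0 - a0, 1e-9 * spread)), np.log(max(b0 - c0, 1e-9 * spread))]
    params = _refine("triangular", p, v, x0, unpack)
    if nonnegative and params["min"] < 0:
        logger.info("triangular fit implied min %.4g < 0; refitting with support truncated at 0",
                    params["min"])

        def unpack0(x):
            c = np.exp(x[0])
            return {"min": 0.0, "mode": float(c), "max": float(c + np.exp(x[1]))}

        params = _refine("triangular", p, v,
                         [np.log(max(c0, 1e-9 * spread)), np.log(max(b0 - c0, 1e-9 * spread))],
                         unpack0)
    return params


_FITTERS = {
    "gamma": _fit_gamma,
    "lognormal": _fit_lognormal,
    "weibull": _fit_weibull,
    "normal": _fit_normal,
    "triangular": _fit_triangular,
    "uniform": _fit_uniform,
}


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FittedDistribution:
    """A gallery family with parameters matched to reported percentiles."""

    family: str
    params: dict
    fit_error: float
    anchors: tuple[tuple[float, float], ...]
    candidates: dict = field(default_factory=dict, repr=False, compare=False)

    def quantile(self, q):
        """Inverse CDF; *q* in (0, 1), scalar or array."""
        if self.family == "point":
            return np.full_like(np.asarray(q, dtype=float), self.params["value"])
        return _frozen(self.family, self.params).ppf(q)

    @classmethod
    def point_mass(cls, value: float) -> "FittedDistribution":
        """Degenerate distribution; useful for deterministic cross-checks."""
        return cls(family="point", params={"value": float(value)}, fit_error=0.0,
                   anchors=((50.0, float(value)),))


def _validate_anchors(anchors) -> tuple[np.ndarray, np.ndarray]:
    anchors = sorted((float(r), float(v)) for r, v in anchors)
    if len(anchors) != 3:
        raise AnchorError(f"exactly three anchors required, got {len(anchors)}")
    ranks = np.array([r for r, _ in anchors])
    values = np.array([v for _, v in anchors])
    if not (0 < ranks[0] < ranks[1] < ranks[2] < 100):
        raise AnchorError(f"ranks must be strictly increasing in (0, 100), got {ranks}")
    if np.any(values <= 0):
        raise AnchorError(f"anchor values must be positive, got {values}")
    if not (values[0] < values[1] < values[2]):
        raise AnchorError(f"anchor values must be strictly increasing, got {values}")
    if (values[2] - values[0]) / values[1] < 1e-6:
        raise AnchorError(f"anchors nearly degenerate: {values}; fit is ill-posed")
    return ranks, values


def fit_from_percentiles(
    anchors: Sequence[tuple[float, float]],
    gallery: Sequence[str] = GALLERY_ORDER,
    nonnegative: bool = True,
) -> FittedDistribution:
    """Best-fitting gallery family for three (rank, value) anchor percentiles.

    Every family in *gallery* is fitted by minimising the sum of squared
    relative quantile deviations at the anchors; families whose optimiser
    fails are skipped with a warning.  The family with the smallest
    objective is returned, ties broken by gallery order.  ``nonnegative``
    truncates a triangular support that would extend below zero (urinary
    levels and percentages are nonnegative quantities).
    """
    ranks, values = _validate_anchors(anchors)
    unknown = set(gallery) - set(GALLERY_ORDER)
    if unknown:
        raise ConfigurationError(f"unknown gallery families {sorted(unknown)}")
    p = ranks / 100.0

    candidates: dict[str, tuple[dict, float]] = {}
    for family in [f for f in GALLERY_ORDER if f in gallery]:
        try:
            if family == "triangular":
                params = _fit_triangular(p, values, nonnegative=nonnegative)
            else:
                params = _FITTERS[family](p, values)
            err = _fit_error(family, params, p, values)
        except (UndefinedFitError, FloatingPointError, ValueError) as exc:
            warnings.warn(f"{family} fit skipped: {exc}", stacklevel=2)
            continue
        if not np.isfinite(err):
            warnings.warn(f"{family} fit produced non-finite error; skipped", stacklevel=2)
            continue
        candidates[family] = (params, err)

    if not candidates:
        raise UndefinedFitError("no gallery family could be fitted to the anchors")
    best_err = min(err for _, err in candidates.values())
    for family in GALLERY_ORDER:
        if family in candidates and candidates[family][1] <= best_err + TIE_TOLERANCE:
            params, err = candidates[family]
            return FittedDistribution(
                family=family, params=params, fit_error=err,
                anchors=tuple(zip(ranks, values)), candidates=candidates,
            )
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSummary:
    mean: float
    sd: float
    percentiles: dict[float, float]


@dataclass(frozen=True)
class MonteCarloResult:
    n_iterations: int
    seed: int | None
    threshold: float
    substance_summaries: dict[str, SampleSummary]
    total_summary: SampleSummary
    exceedance: float
    clip_fractions: dict[str, float]
    samples: dict | None = None


def _summarise(x: np.ndarray, grid=(5, 25, 50, 75, 95)) -> SampleSummary:
    return SampleSummary(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        percentiles={float(g): float(np.percentile(x, g)) for g in grid},
    )


def run_monte_carlo(
    level_dist: FittedDistribution,
    contribution_dists: Mapping[str, FittedDistribution],
    hbm_gvs: Mapping[str, float],
    n: int = 10_000,
    seed: int | None = None,
    threshold: float = 1.0,
    renormalize: bool = False,
    keep_samples: bool = False,
) -> MonteCarloResult:
    """Propagate level and contribution variability into hazard quotients.

    Per iteration: draw a population urinary level ``L`` (clipped at 0),
    then a contribution percent per substance (clipped to [0, 100],
    optionally renormalised to sum 100), and compute
    ``HQ_s = L * p_s / 100 / HBM-GV_s`` with the total as their sum.
    Draws are inverse-transform from one ``numpy`` generator seeded with
    *seed*: the level consumes the first block of uniforms, then each
    substance in the mapping's iteration order.  Identical seeds give
    bit-identical results.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if not contribution_dists:
        raise ConfigurationError("contribution_dists must not be empty")
    missing = set(contribution_dists) - set(hbm_gvs)
    if missing:
        raise ConfigurationError(f"missing HBM-GVs for {sorted(missing)}")
    for s, gv in hbm_gvs.items():
        if s in contribution_dists and gv <= 0:
            raise ConfigurationError(f"HBM-GV for {s} must be positive, got {gv}")
    for name, dist in {"level": level_dist, **contribution_dists}.items():
        if not isinstance(dist, FittedDistribution):
            raise ConfigurationError(f"{name}: expected a FittedDistribution, got {type(dist)!r}")

    rng = np.random.default_rng(seed)
    levels = np.asarray(level_dist.quantile(rng.random(n)), dtype=float)
    clip_fractions = {"level": float(np.mean(levels < 0))}
    levels = np.clip(levels, 0.0, None)

    percents = {}
    for substance, dist in contribution_dists.items():
        draw = np.asarray(dist.quantile(rng.random(n)), dtype=float)
        clip_fractions[substance] = float(np.mean((draw < 0) | (draw > 100)))
        percents[substance] = np.clip(draw, 0.0, 100.0)

    for name, frac in clip_fractions.items():
        if frac > 0.005:
            logger.warning("%.2f%% of %s draws required clipping", 100 * frac, name)

    if renormalize:
        total_pct = np.sum(list(percents.values()), axis=0)
        scale = np.where(total_pct > 0, 100.0 / total_pct, 1.0)
        percents = {s: p * scale for s, p in percents.items()}

    hq = {s: levels * percents[s] / 100.0 / hbm_gvs[s] for s in percents}
    total = np.sum(list(hq.values()), axis=0)

    return MonteCarloResult(
        n_iterations=n,
        seed=seed,
        threshold=threshold,
        substance_summaries={s: _summarise(x) for s, x in hq.items()},
        total_summary=_summarise(total),
        exceedance=float(np.mean(total > threshold)),
        clip_fractions=clip_fractions,
        samples={"level": levels, "hq": hq, "total": total} if keep_samples else None,
    )
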