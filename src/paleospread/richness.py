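"""Species-richness estimation for occurrence pools.

Three estimators are provided for each pool (a region x time bin, or one
equal-spread spatial sample):

* raw richness — the face-value count of distinct taxa;
* SQS (shareholder quorum subsampling) — coverage-based rarefaction that
  draws whole collections in random order until the drawn taxa account for a
  fixed share (the quorum, corrected by Good's u) of the pool's
  occurrence-frequency distribution;
* TRiPS — a parametric estimate that models the number of times each species
  is sampled as a Poisson process, fits the sampling rate by maximum
  likelihood on the zero-truncated counts, and divides observed richness by
  the implied detection probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import betaln, gammaln

from .occurrence_io import OccurrenceRecord, PoolDiagnostics, pool_diagnostics

__all__ = [
    "SQSConfig",
    "TripsEstimate",
    "RichnessEstimate",
    "goods_u",
    "sqs_trial_richness",
    "sqs_richness",
    "ztp_lambda_mle",
    "ztp_lambda_profile_ci",
    "trips_richness",
    "estimate_pool",
    "estimate_all",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class SQSConfig:
    quorum: float = 0.4
    n_trials: int = 100
    singleton_rule: Literal["by_collection", "by_occurrence"] = "by_collection"
    exclude_dominant: bool = False


def _pool_structure(pool: Sequence[OccurrenceRecord]):
    """(collections: id -> taxa list, taxon occurrence counts, taxon collections)."""
    colls: dict[str, list[str]] = {}
    counts: dict[str, int] = {}
    taxon_colls: dict[str, set[str]] = {}
    for r in pool:
        colls.setdefault(r.collection_id, []).append(r.taxon_name)
        counts[r.taxon_name] = counts.get(r.taxon_name, 0) + 1
        taxon_colls.setdefault(r.taxon_name, set()).add(r.collection_id)
    return colls, counts, taxon_colls


def goods_u(
    pool: Sequence[OccurrenceRecord],
    singleton_rule: Literal["by_collection", "by_occurrence"] = "by_collection",
) -> float | None:
    """Good's u coverage estimate: 1 - singletons / occurrences.

    With the default rule a singleton is a taxon found in exactly one
    collection; ``by_occurrence`` counts taxa with exactly one occurrence.
    Returns None for an empty pool.  Clamped to [0, 1].
    """
    if not pool:
        return None
    _, counts, taxon_colls = _pool_structure(pool)
    if singleton_rule == "by_collection":
        singletons = sum(1 for cs in taxon_colls.values() if len(cs) == 1)
    else:
        singletons = sum(1 for k in counts.values() if k == 1)
    return min(1.0, max(0.0, 1.0 - singletons / len(pool)))


def sqs_trial_richness(
    pool: Sequence[OccurrenceRecord],
    collection_order: Sequence[str],
    cfg: SQSConfig,
    u: float,
) -> int:
    """Richness of one deterministic SQS trial given a collection order.

    Whole collections are drawn in the given order; after each draw the
    coverage of the drawn taxa is the sum of their full-pool frequency
    shares, scaled by Good's u to refer to the true underlying pool.  Drawing
    stops once coverage reaches the quorum; the trial's richness is the
    number of distinct taxa drawn.  Exposed separately so tests can
    enumerate all collection orders exhaustively.
    """
    colls, counts, _ = _pool_structure(pool)
    total = sum(counts.values())
    dominant = max(counts, key=lambda t: (counts[t], t)) if cfg.exclude_dominant else None
    seen: set[str] = set()
    coverage = 0.0
    for cid in collection_order:
        for t in colls[cid]:
            if t not in seen:
                seen.add(t)
                if t != dominant:
                    coverage += u * counts[t] / total
        if coverage >= cfg.quorum:
            break
    return len(seen)


def sqs_richness(
    pool: Sequence[OccurrenceRecord],
    cfg: SQSConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float] | None:
    """Mean (and SD) of subsampled richness over ``cfg.n_trials`` SQS trials.

    Returns None when the pool is empty or its Good's u falls below the
    quorum (the pool cannot support the requested coverage).
    """
    cfg = cfg or SQSConfig()
    if not pool:
        return None
    u = goods_u(pool, cfg.singleton_rule)
    if u is None or u < cfg.quorum or u == 0.0:
        return None
    rng = np.random.default_rng(rng)
    coll_ids = sorted({r.collection_id for r in pool})
    richness = np.empty(cfg.n_trials)
    for i in range(cfg.n_trials):
        order = list(rng.permutation(coll_ids))
        richness[i] = sqs_trial_richness(pool, order, cfg, u)
    return float(richness.mean()), float(richness.std(ddof=1)) if cfg.n_trials > 1 else 0.0


# ---------------------------------------------------------------- TRiPS ----


def ztp_lambda_mle(counts: Sequence[int]) -> float:
    """Zero-truncated-Poisson MLE of the sampling intensity lambda.

    Solves lambda / (1 - exp(-lambda)) = mean(counts) by bracketed root
    finding to |residual| < 1e-10.  All counts must be >= 1.  When the mean
    is 1 (every taxon a single occurrence) the MLE sits at the lambda -> 0
    boundary and 0.0 is returned (callers flag the estimate degenerate).
    """
    counts = np.asarray(counts)
    if counts.size == 0 or np.any(counts < 1):
        raise ValueError("counts must be non-empty with all values >= 1")
    m = float(counts.mean())
    if m <= 1.0:
        return 0.0

    def g(lam: float) -> float:
        return lam / (1.0 - math.exp(-lam)) - m

    hi = m  # lam/(1-e^-lam) > lam, so the root lies below the mean
    lo = 1e-12
    return float(brentq(g, lo, hi + 1.0, xtol=1e-12, rtol=8.9e-16))


def _ztp_loglik(lam: float, counts: np.ndarray) -> float:
    if lam <= 0:
        return -np.inf
    n = counts.size
    return float(
        counts.sum() * math.log(lam)
        - n * lam
        - n * math.log1p(-math.exp(-lam))
        - gammaln(counts + 1).sum()
    )


def ztp_lambda_profile_ci(
    counts: Sequence[int], cutoff: float = 3.84
) -> tuple[float, float, float]:
    """(lambda_hat, lo, hi): profile-likelihood CI with chi2(1) cutoff.

    The interval is the set of lambda whose log-likelihood lies within
    cutoff/2 of the maximum (3.84 gives a 95% interval).
    """
    counts = np.asarray(counts)
    lam_hat = ztp_lambda_mle(counts)
    if lam_hat == 0.0:
        return 0.0, 0.0, 0.0
    ll_max = _ztp_loglik(lam_hat, counts)
    drop = cutoff / 2.0

    def f(lam: float) -> float:
        return _ztp_loglik(lam, counts) - (ll_max - drop)

    lo_bracket = lam_hat
    while f(lo_bracket) > 0 and lo_bracket > 1e-10:
        lo_bracket /= 2.0
    lo = brentq(f, lo_bracket, lam_hat) if f(lo_bracket) <= 0 else 0.0
    hi_bracket = lam_hat * 2 + 1.0
    while f(hi_bracket) > 0:
        hi_bracket *= 2.0
    hi = brentq(f, lam_hat, hi_bracket)
    return lam_hat, float(lo), float(hi)


def _binom_n_profile_bounds(n_obs: int, p: float, drop: float = 1.92) -> tuple[int, int]:
    """Profile-likelihood bounds on binomial N given n_obs successes at rate p."""
    if p >= 1.0:  # certain detection: N is known exactly
        return n_obs, n_obs

    def ll(N: int) -> float:
        if N < n_obs:
            return -np.inf
        return (
            -betaln(N - n_obs + 1, n_obs + 1)
            - math.log(N + 1)
            + n_obs * math.log(p)
            + (N - n_obs) * math.log1p(-p)
        )

    n_hat = max(n_obs, int(math.floor(n_obs / p)))
    ll_max = max(ll(n_hat), ll(n_hat + 1))
    lo = n_hat
    while lo > n_obs and ll(lo - 1) >= ll_max - drop:
        lo -= 1
    hi = n_hat
    while ll(hi + 1) >= ll_max - drop:
        hi += 1
    return lo, hi


@dataclass(frozen=True)
class TripsEstimate:
    lambda_hat: float
    p_hat: float
    n_observed: int
    richness_hat: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def trips_richness(counts: Sequence[int]) -> TripsEstimate:
    """TRiPS richness from per-taxon occurrence counts.

    lambda is the per-bin sampling intensity; detection probability
    p = 1 - exp(-lambda); richness_hat = n_observed / p.  The 95% CI
    combines the profile-likelihood interval on lambda with the binomial
    uncertainty in how many of the true N species were detected: the lower
    bound assumes the most optimistic detection rate (n_obs / p_high) and
    the upper bound inverts the binomial likelihood in N at p_low.
    """
    counts = np.asarray(counts)
    n_obs = int(counts.size)
    lam, lam_lo, lam_hi = ztp_lambda_profile_ci(counts)
    if lam == 0.0:
        return TripsEstimate(0.0, 0.0, n_obs, math.inf, n_obs, math.inf, degenerate=True)
    p_hat = 1.0 - math.exp(-lam)
    p_lo = 1.0 - math.exp(-lam_lo) if lam_lo > 0 else 0.0
    p_hi = 1.0 - math.exp(-lam_hi)
    rich = n_obs / p_hat
    ci_low = n_obs / p_hi
    if p_lo > 0.0:
        _, ci_high = _binom_n_profile_bounds(n_obs, p_lo)
    else:
        ci_high = math.inf
    return TripsEstimate(
        lambda_hat=lam,
        p_hat=p_hat,
        n_observed=n_obs,
        richness_hat=rich,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


@dataclass
class RichnessEstimate:
    """Bundle of raw, SQS and TRiPS richness for one pool."""

    region: str
    bin: str
    replicate_id: int | str
    raw: int
    sqs_mean: float | None
    sqs_sd: float | None
    trips: TripsEstimate | None
    diagnostics: PoolDiagnostics = field(default=None)


def estimate_pool(
    pool: Sequence[OccurrenceRecord],
    region: str = "",
    bin_name: str = "",
    replicate_id: int | str = "regional",
    sqs_cfg: SQSConfig | None = None,
    rng: np.random.Generator | int | None = None,
    run_trips: bool = True,
) -> RichnessEstimate:
    """Raw + SQS + TRiPS estimates and diagnostics for one pool."""
    diag = pool_diagnostics(pool)
    sqs = sqs_richness(pool, sqs_cfg, rng)
    trips = None
    if run_trips and diag.raw_richness >= 2:
        _, counts, _ = _pool_structure(pool)
        est = trips_richness(list(counts.values()))
        trips = None if est.degenerate else est
    return RichnessEstimate(
        region=region,
        bin=bin_name,
        replicate_id=replicate_id,
        raw=diag.raw_richness,
        sqs_mean=None if sqs is None else sqs[0],
        sqs_sd=None if sqs is None else sqs[1],
        trips=trips,
        diagnostics=diag,
    )


def estimate_all(
    pools: dict,
    sqs_cfg: SQSConfig | None = None,
    master_seed: int = 0,
    run_trips: bool = True,
) -> list[RichnessEstimate]:
    """Estimate richness for many pools at once.

    ``pools`` maps ``(region, bin)`` to either one occurrence pool
    (unstandardized mode: one estimate) or a list of replicate pools
    (standardized mode: per-replicate estimates plus their aggregate).
    Pools where every estimator is unavailable still yield a row with the
    raw count, so missingness is visible downstream.
    """
    ss = np.random.SeedSequence(master_seed)
    streams = ss.spawn(len(pools))
    out: list[RichnessEstimate] = []
    for ((region, bin_name), pool), child in zip(sorted(pools.items()), streams):
        rng = np.random.default_rng(child)
        if pool and isinstance(pool[0], OccurrenceRecord):
            out.append(
                estimate_pool(pool, region, bin_name, "regional", sqs_cfg, rng, run_trips)
            )
            continue
        reps = [
            estimate_pool(p, region, bin_name, i, sqs_cfg, rng, run_trips)
            for i, p in enumerate(pool)
        ]
        out.extend(reps)
        agg = aggregate_replicates(reps)
        if agg is not None:
            out.append(agg)
    return out


def aggregate_replicates(
    estimates: Sequence[RichnessEstimate],
) -> RichnessEstimate | None:
    """Mean across accepted replicate estimates of one region x bin.

    Each component (raw, SQS, TRiPS richness) is averaged over the
    replicates where it is defined; SD across replicates replaces the
    within-trial SD.  Returns None when no replicate produced any estimate.
    """
    if not estimates:
        return None
    region, bin_name = estimates[0].region, estimates[0].bin
    raws = [e.raw for e in estimates]
    sqs_vals = [e.sqs_mean for e in estimates if e.sqs_mean is not None]
    trips_vals = [e.trips.richness_hat for e in estimates if e.trips is not None]
    trips_agg = None
    if trips_vals:
        lo = float(np.mean([e.trips.ci_low for e in estimates if e.trips is not None]))
        hi = float(np.mean([e.trips.ci_high for e in estimates if e.trips is not None]))
        lam = float(np.mean([e.trips.lambda_hat for e in estimates if e.trips is not None]))
        nob = float(np.mean([e.trips.n_observed for e in estimates if e.trips is not None]))
        trips_agg = TripsEstimate(
            lam, 1.0 - math.exp(-lam), int(round(nob)),
            float(np.mean(trips_vals)), lo, hi,
        )
    # diagnostics: keep those of the first replicate as representative
    return RichnessEstimate(
        region=region,
        bin=bin_name,
        replicate_id="aggregated",
        raw=int(round(np.mean(raws))),
        sqs_mean=float(np.mean(sqs_vals)) if sqs_vals else None,
        sqs_sd=float(np.std(sqs_vals, ddof=1)) if len(sqs_vals) > 1 else (0.0 if sqs_vals else None),
        trips=trips_agg,
        diagnostics=estimates[0].diagnostics,
    )
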