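"""Synthetic fossil-occurrence worlds with known truth.

The generator builds toy occurrence tables with the structural features that
drive the species-area artefact in real fossil data: species with finite
geographic ranges and uneven abundances, collections (localities) clustered
in space by a Thomas-style parent/offspring process, collections grouped
into references, and ages nested inside a time-bin scheme.  Because each
world records its ground truth (per-bin true richness, species ranges), every
pipeline stage can be tested end to end without external data.

Scale defaults are deliberately small (a few hundred occurrences per bin) so
whole-pipeline simulations run in seconds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .occurrence_io import OccurrenceRecord, TaxonRank, TimeBin
from .spatial_metrics import EARTH_RADIUS_KM, great_circle_km, normalize_lon

__all__ = [
    "WorldConfig",
    "generate_world",
    "generate_trips_counts",
    "heterogeneous_sampling_scenario",
    "default_toy_bins",
    "write_truth",
]

KM_PER_DEG = math.pi * EARTH_RADIUS_KM / 180.0  # ~111.19


def default_toy_bins(n_bins: int = 8, start_ma: float = 138.0, duration: float = 9.0):
    """A generic scheme of equal 9-myr bins (oldest first), B1..Bn."""
    return [
        TimeBin(f"B{i + 1}", start_ma - i * duration, start_ma - (i + 1) * duration)
        for i in range(n_bins)
    ]


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of one synthetic world.

    The bounding box is the species' biogeographic domain; collections are
    sampled from a window centred in it whose half-size is
    ``base_window_frac * spread_multiplier[bin]`` of the box half-size, so
    per-bin multipliers directly control the palaeogeographic spread of
    sampling while the underlying fauna stays fixed.  The number of
    collections in a bin scales with the window's area (``n_collections *
    multiplier**2``), keeping sampling density constant: a more widely
    sampled interval has proportionally more localities, which is the
    empirical regularity that makes raw richness track spread.
    """

    n_species: int = 150
    abundance_model: tuple = ("lognormal", 0.0, 1.0)  # or ("log_series", theta)
    lat_bounds: tuple[float, float] = (20.0, 60.0)
    lon_bounds: tuple[float, float] = (-40.0, 40.0)
    range_radius_log_mu: float = math.log(1500.0)  # km
    range_radius_log_sigma: float = 0.5
    n_collections: int = 40  # per bin
    n_parents: int = 8
    offspring_sd_km: float = 150.0
    occ_per_collection: float = 6.0  # Poisson mean, floored at 1
    refs_mean: float = 2.0  # collections per reference ~ 1 + Poisson(mean)
    bins: tuple = field(default_factory=lambda: tuple(default_toy_bins()))
    trajectory: tuple = ("constant",)  # or ("exponential", rate), ("step", factor, at_bin)
    base_window_frac: float = 0.5
    spread_multipliers: tuple | None = None  # per bin; None -> all 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_species < 1 or self.n_collections < 1 or self.n_parents < 1:
            raise ValueError("counts must be >= 1")
        if self.range_radius_log_sigma < 0 or self.occ_per_collection <= 0:
            raise ValueError("invalid noise/abundance parameters")
        if self.spread_multipliers is not None:
            if len(self.spread_multipliers) != len(self.bins):
                raise ValueError("need one spread multiplier per bin")
            if any(m <= 0 for m in self.spread_multipliers):
                raise ValueError("spread multipliers must be positive")


def _abundances(cfg: WorldConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = cfg.abundance_model[0]
    if kind == "lognormal":
        _, mu, sigma = cfg.abundance_model
        w = rng.lognormal(mu, sigma, n)
    elif kind == "log_series":
        theta = cfg.abundance_model[1]
        if not 0 < theta < 1:
            raise ValueError("log_series theta must be in (0,1)")
        ranks = np.arange(1, n + 1)
        w = theta**ranks / ranks  # Fisher log-series rank-abundance shape
    else:
        raise ValueError(f"unknown abundance model {kind!r}")
    return w / w.sum()


def _trajectory_counts(cfg: WorldConfig) -> list[int]:
    """Active species count per bin; the max across bins equals the pool size."""
    kind = cfg.trajectory[0]
    mids = [b.midpoint_ma for b in cfg.bins]
    if kind == "constant":
        factors = [1.0] * len(mids)
    elif kind == "exponential":
        rate = cfg.trajectory[1]
        youngest = min(mids)
        factors = [math.exp(-rate * (t - youngest)) for t in mids]
    elif kind == "step":
        factor, at_bin = cfg.trajectory[1], cfg.trajectory[2]
        names = [b.name for b in cfg.bins]
        cut = names.index(at_bin) if isinstance(at_bin, str) else int(at_bin)
        factors = [1.0 if i < cut else factor for i in range(len(mids))]
    else:
        raise ValueError(f"unknown trajectory {kind!r}")
    peak = max(factors)
    return [max(1, round(cfg.n_species * f / peak)) for f in factors]


def generate_world(
    cfg: WorldConfig,
) -> tuple[list[OccurrenceRecord], dict]:
    """Generate one world: (occurrence records, truth record).

    Species get circular great-circle ranges (centre uniform in the bounding
    box, radius lognormal) and fixed relative abundances.  Per bin, the
    active species are the first k of the pool (k from the richness
    trajectory); collections are scattered around uniformly-placed parent
    points inside the bin's sampling window, and each collection's
    occurrences are drawn from the active species whose range covers it,
    weighted by abundance.  A collection covered by no species is relocated
    (up to 1,000 tries).  Identical configs (including seed) give identical
    worlds.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    pool = max(_trajectory_counts(cfg))
    names = [f"Synthetica species{i:04d}" for i in range(pool)]
    lat0, lat1 = cfg.lat_bounds
    lon0, lon1 = cfg.lon_bounds
    centres = np.column_stack(
        [rng.uniform(lat0, lat1, pool), rng.uniform(lon0, lon1, pool)]
    )
    radii = rng.lognormal(cfg.range_radius_log_mu, cfg.range_radius_log_sigma, pool)
    abund = _abundances(cfg, pool, rng)
    k_per_bin = _trajectory_counts(cfg)
    multipliers = cfg.spread_multipliers or tuple([1.0] * len(cfg.bins))

    clat, clon = 0.5 * (lat0 + lat1), 0.5 * (lon0 + lon1)
    base_hw_lat = 0.5 * (lat1 - lat0) * cfg.base_window_frac
    base_hw_lon = 0.5 * (lon1 - lon0) * cfg.base_window_frac

    records: list[OccurrenceRecord] = []
    occ_no = 0
    truth_bins = {}
    for b, k, m in zip(cfg.bins, k_per_bin, multipliers):
        hw_lat = min(base_hw_lat * m, 0.5 * (lat1 - lat0))
        hw_lon = min(base_hw_lon * m, 0.5 * (lon1 - lon0))
        wlat = (clat - hw_lat, clat + hw_lat)
        wlon = (clon - hw_lon, clon + hw_lon)
        active = slice(0, k)
        # sampling regime is spatially stationary: localities and cluster
        # parents both scale with window area, so density and clustering
        # look the same in every bin
        n_coll = max(4, round(cfg.n_collections * m * m))
        n_parents = max(2, round(cfg.n_parents * m * m))
        parents = np.column_stack(
            [rng.uniform(*wlat, n_parents), rng.uniform(*wlon, n_parents)]
        )
        # references: consecutive collections grouped into blocks
        ref_of: list[int] = []
        ref_id = 0
        while len(ref_of) < n_coll:
            size = 1 + rng.poisson(cfg.refs_mean)
            ref_of.extend([ref_id] * size)
            ref_id += 1
        for c in range(n_coll):
            covering = None
            lat = lon = 0.0
            for _ in range(1000):
                p = parents[int(rng.integers(n_parents))]
                lat = float(
                    np.clip(p[0] + rng.normal(0, cfg.offspring_sd_km / KM_PER_DEG), *wlat)
                )
                lon_scale = cfg.offspring_sd_km / (
                    KM_PER_DEG * max(0.1, math.cos(math.radians(lat)))
                )
                lon = float(np.clip(p[1] + rng.normal(0, lon_scale), *wlon))
                dists = np.array(
                    [great_circle_km((lat, lon), tuple(ctr)) for ctr in centres[active]]
                )
                idx = np.where(dists <= radii[active])[0]
                if idx.size:
                    covering = idx
                    break
            if covering is None:
                raise RuntimeError(
                    "could not place a collection inside any species range; "
                    "increase range radii or window overlap"
                )
            w = abund[covering]
            n_occ = max(1, int(rng.poisson(cfg.occ_per_collection)))
            drawn = rng.choice(covering, size=n_occ, p=w / w.sum())
            mid = float(rng.uniform(b.end_ma, b.start_ma))
            half = 0.5
            max_ma = min(b.start_ma, mid + half)
            min_ma = max(b.end_ma, mid - half)
            coll_id = f"c{b.name}_{c}"
            for sp in drawn:
                records.append(
                    OccurrenceRecord(
                        occurrence_id=f"o{occ_no}",
                        taxon_name=names[int(sp)],
                        taxon_rank=TaxonRank.SPECIES,
                        collection_id=coll_id,
                        reference_id=f"r{b.name}_{ref_of[c]}",
                        palaeolat=lat,
                        palaeolon=normalize_lon(lon),
                        interval_max_ma=max_ma,
                        interval_min_ma=min_ma,
                    )
                )
                occ_no += 1
        truth_bins[b.name] = {
            "true_richness": int(k),
            "spread_multiplier": float(m),
            "n_collections": int(n_coll),
            "window_lat": list(wlat),
            "window_lon": list(wlon),
        }
    truth = {
        "per_bin": truth_bins,
        "species": [
            {
                "name": names[i],
                "centre": [float(centres[i, 0]), float(centres[i, 1])],
                "radius_km": float(radii[i]),
                "abundance": float(abund[i]),
            }
            for i in range(pool)
        ],
        "rng_seed": cfg.rng_seed,
    }
    return records, truth


def generate_trips_counts(
    n_species: int, lam: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Per-taxon sampling counts under the TRiPS model, zeros dropped.

    Each of ``n_species`` true species is sampled Poisson(lam) times; the
    unobserved (zero-count) species vanish, exactly the censoring TRiPS
    inverts.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    rng = np.random.default_rng(rng)
    counts = rng.poisson(lam, n_species)
    return counts[counts > 0]


def heterogeneous_sampling_scenario(
    cfg: WorldConfig, spread_multipliers: Sequence[float]
) -> WorldConfig:
    """A world whose true richness is constant while sampled spread varies.

    Returns a config with a constant richness trajectory and the given
    per-bin spread multipliers — the ingredients of the species-area
    artefact: raw richness tracks spread even though the fauna never
    changes.
    """
    return replace(
        cfg,
        trajectory=("constant",),
        spread_multipliers=tuple(float(m) for m in spread_multipliers),
    )


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
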