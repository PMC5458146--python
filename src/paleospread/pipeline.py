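"""End-to-end workflow: occurrence CSV -> cleaned pools -> equal-spread
samples -> richness tables -> trend fits.

Every stage is a pure function of its inputs plus the master seed, so a rerun
with the same config is byte-identical.  Partial failures (unsampleable
subtrees, degenerate estimates, pools below the quorum) are recorded in the
outputs, never fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import occurrence_io as oio
from .occurrence_io import FilterConfig, OccurrenceRecord, TimeBin
from .richness import (
    RichnessEstimate,
    SQSConfig,
    aggregate_replicates,
    estimate_pool,
)
from .spatial_metrics import SpatialPool, bin_to_grid, build_mst
from .spatial_subsampling import (
    RegionalSubtree,
    remove_barrier_edges,
    replicate_spatial_samples,
    split_global_mst,
)
from .trends import TrendFit, bonferroni, fit_trend

logger = logging.getLogger("paleospread")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    input_csv: str | None = None
    bin_scheme_csv: str | None = None  # None -> packaged Tr1-Pg2 scheme
    barriers_csv: str | None = None  # optional CSV: lat_a,lon_a,lat_b,lon_b cell indices
    cell_deg: float = 1.0
    ceiling_km: float = 13_000.0
    target_km: float = 3_200.0
    tolerance: float = 0.10
    n_reps: int = 20
    sqs: SQSConfig = field(default_factory=SQSConfig)
    run_trips: bool = True
    min_refs: int = 20
    collapse_duplicates: bool = True
    master_seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        for p in (self.input_csv, self.bin_scheme_csv, self.barriers_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not 0 < self.cell_deg <= 90:
            raise ValueError("cell_deg must be in (0, 90]")
        if self.target_km <= 0 or self.ceiling_km <= 0 or not 0 < self.tolerance < 1:
            raise ValueError("invalid spread parameters")
        if self.n_reps < 1 or self.min_refs < 0:
            raise ValueError("invalid n_reps/min_refs")

    def config_hash(self) -> str:
        payload = {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    cleaned: list
    cleaning_tally: dict
    pools: list  # SpatialPool per bin (global)
    subtrees: dict  # bin -> list[RegionalSubtree]
    manifest: pd.DataFrame
    richness: pd.DataFrame
    trends: pd.DataFrame


def _load_barriers(path: str | None):
    if path is None:
        return []
    df = pd.read_csv(path)
    return [
        (
            (int(r["lat_a"]), int(r["lon_a"])),
            (int(r["lat_b"]), int(r["lon_b"])),
        )
        for _, r in df.iterrows()
    ]


def _collections_of(records: Sequence[OccurrenceRecord]) -> dict:
    return {r.collection_id: (r.palaeolat, r.palaeolon) for r in records}


def _est_row(est: RichnessEstimate, mode: str, min_refs: int) -> dict:
    d = est.diagnostics
    return {
        "region": est.region,
        "bin": est.bin,
        "mode": mode,
        "replicate": est.replicate_id,
        "raw": est.raw,
        "sqs_mean": est.sqs_mean,
        "sqs_sd": est.sqs_sd,
        "trips_hat": est.trips.richness_hat if est.trips else None,
        "trips_lo": est.trips.ci_low if est.trips else None,
        "trips_hi": est.trips.ci_high if est.trips else None,
        "u": d.goods_u,
        "dominance": d.dominance,
        "n_occ": d.n_occurrences,
        "n_coll": d.n_collections,
        "n_refs": d.n_references,
        "reportable": d.n_references >= min_refs,
    }


def run_pipeline(
    config: PipelineConfig,
    records: Sequence[OccurrenceRecord] | None = None,
    bins: Sequence[TimeBin] | None = None,
    filters: FilterConfig | None = None,
) -> PipelineResult:
    """Run the full workflow.

    ``records``/``bins`` may be passed in memory (e.g. from the synthetic
    generator); otherwise they are read from the configured paths.  Outputs
    are returned as DataFrames and, when ``config.output_dir`` is set, also
    written as CSV/JSON alongside a run log.
    """
    config.validate()
    logger.info("pipeline start, config hash %s", config.config_hash())

    # ---- clean -------------------------------------------------------
    if records is None:
        if config.input_csv is None:
            raise ValueError("either records or config.input_csv is required")
        records, errors = oio.read_occurrence_table(config.input_csv)
        logger.info("read %d records, %d malformed rows", len(records), len(errors))
    records = list(records)
    records, tally = oio.apply_taxon_filters(records, filters)
    if config.collapse_duplicates:
        before = len(records)
        records = oio.collapse_duplicates(records)
        tally["duplicates_collapsed"] = before - len(records)
    if bins is None:
        bins = (
            oio.load_bin_scheme(config.bin_scheme_csv)
            if config.bin_scheme_csv
            else oio.default_bin_scheme()
        )
    records = oio.assign_time_bins(records, bins)
    by_bin: dict[str, list[OccurrenceRecord]] = {}
    for r in records:
        if r.time_bin is not None:
            by_bin.setdefault(r.time_bin, []).append(r)
    logger.info("cleaned: %d records in %d bins", len(records), len(by_bin))

    barriers = _load_barriers(config.barriers_csv)
    bin_by_name = {b.name: b for b in bins}
    master = np.random.SeedSequence(config.master_seed)
    bin_streams = dict(zip([b.name for b in bins], master.spawn(len(bins))))

    pools: list[SpatialPool] = []
    subtrees_by_bin: dict[str, list[RegionalSubtree]] = {}
    manifest_rows = []
    richness_rows: list[dict] = []
    min_km = config.target_km * (1 - config.tolerance)

    for b in bins:
        recs = by_bin.get(b.name)
        if not recs:
            continue
        cells = bin_to_grid(_collections_of(recs), config.cell_deg)
        pool = SpatialPool.from_cells("global", b.name, cells)
        pools.append(pool)
        colls_by_cell = {c.cell_id: c.member_collections for c in cells}
        recs_by_coll: dict[str, list[OccurrenceRecord]] = {}
        for r in recs:
            recs_by_coll.setdefault(r.collection_id, []).append(r)

        edges, _ = build_mst(cells)
        subtrees = split_global_mst(
            cells, edges, b.name, config.ceiling_km,
            min_km=min_km, target_km=config.target_km, tolerance=config.tolerance,
        )
        if barriers:
            subtrees, warns = remove_barrier_edges(subtrees, barriers, min_km)
            for w in warns:
                logger.warning("%s: %s", b.name, w)
        subtrees_by_bin[b.name] = subtrees

        ss_children = bin_streams[b.name].spawn(2 * max(1, len(subtrees)))
        for k, st in enumerate(subtrees):
            # unstandardized (regional) estimate over the whole subtree
            st_colls = set().union(*(colls_by_cell[c.cell_id] for c in st.cells))
            regional_pool = [r for c in st_colls for r in recs_by_coll.get(c, [])]
            sqs_rng = np.random.default_rng(ss_children[2 * k])
            est = estimate_pool(
                regional_pool, st.subtree_id, b.name, "regional",
                config.sqs, sqs_rng, config.run_trips,
            )
            richness_rows.append(_est_row(est, "unstandardized", config.min_refs))

            # standardized: replicate equal-spread samples
            samples = replicate_spatial_samples(
                st, config.n_reps, config.target_km, config.tolerance,
                master_seed=ss_children[2 * k + 1],
            )
            rep_rng = np.random.default_rng(ss_children[2 * k].spawn(1)[0])
            rep_ests = []
            for s in samples:
                manifest_rows.append(
                    {
                        "region": st.subtree_id,
                        "bin": b.name,
                        "replicate_id": s.replicate_id,
                        "seed_cell": str(s.seed_cell),
                        "n_cells": len(s.cells),
                        "induced_mst_km": s.induced_mst_km,
                        "accepted": s.accepted,
                        "reject_reason": s.reject_reason,
                    }
                )
                if not s.accepted:
                    continue
                s_colls = set().union(
                    *(colls_by_cell[c] for c in s.cells)
                ) if s.cells else set()
                s_pool = [r for c in s_colls for r in recs_by_coll.get(c, [])]
                e = estimate_pool(
                    s_pool, st.subtree_id, b.name, s.replicate_id,
                    config.sqs, rep_rng, config.run_trips,
                )
                rep_ests.append(e)
                richness_rows.append(_est_row(e, "replicate", config.min_refs))
            agg = aggregate_replicates(rep_ests)
            if agg is not None:
                richness_rows.append(_est_row(agg, "standardized", config.min_refs))
            elif samples:
                logger.warning("%s %s: unsampleable subtree", b.name, st.subtree_id)

    manifest = pd.DataFrame(
        manifest_rows,
        columns=[
            "region", "bin", "replicate_id", "seed_cell", "n_cells",
            "induced_mst_km", "accepted", "reject_reason",
        ],
    )
    richness = pd.DataFrame(richness_rows)

    trends = _fit_trend_table(richness, bin_by_name, config.min_refs)

    result = PipelineResult(
        config, records, tally, pools, subtrees_by_bin, manifest, richness, trends
    )
    if config.output_dir:
        _write_outputs(result)
    return result


def _fit_trend_table(
    richness: pd.DataFrame, bin_by_name: dict, min_refs: int
) -> pd.DataFrame:
    """Table-style trend fits: one series per (mode, estimator)."""
    rows = []
    fits: list[TrendFit] = []
    if richness.empty:
        return pd.DataFrame()
    for mode in ("unstandardized", "standardized"):
        sub = richness[(richness["mode"] == mode) & richness["reportable"]]
        for est_col, family, label in (
            ("raw", "negative_binomial_log", "raw"),
            ("sqs_mean", "gaussian_log", "sqs"),
            ("trips_hat", "gaussian_log", "trips"),
        ):
            pts = [
                (bin_by_name[r["bin"]].midpoint_ma, r[est_col])
                for _, r in sub.iterrows()
                if pd.notna(r[est_col]) and r[est_col] > 0
            ]
            if len(pts) < 3:
                continue
            try:
                fit = fit_trend(pts, family, f"{mode} ({label})")
            except Exception as exc:  # singular fits on degenerate toy series
                logger.warning("trend fit failed for %s (%s): %s", mode, label, exc)
                continue
            fits.append(fit)
    if not fits:
        return pd.DataFrame()
    # non-finite p (degenerate fits) excluded from the correction, kept as NaN
    finite = [f.p_slope for f in fits if np.isfinite(f.p_slope)]
    corrected_finite, threshold = bonferroni(finite)
    it = iter(corrected_finite)
    corrected = [next(it) if np.isfinite(f.p_slope) else float("nan") for f in fits]
    for f, pc in zip(fits, corrected):
        rows.append(
            {
                "series": f.series_label,
                "family": f.family,
                "slope": f.slope,
                "se": f.se_slope,
                "p": f.p_slope,
                "p_bonferroni": pc,
                "bonferroni_threshold": threshold,
                "df": f.df,
                "ln_increase": f.ln_increase,
                "percent_increase": f.percent_increase,
                "n_points": f.n_points,
            }
        )
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    oio.write_occurrence_table(result.cleaned, out / "cleaned_occurrences.csv")
    oio.write_cleaning_report(result.cleaning_tally, out / "cleaning_report.json")
    pd.DataFrame(
        [
            {"region": p.region_label, "bin": p.bin, **p.metrics.as_dict()}
            for p in result.pools
        ]
    ).to_csv(out / "spread_metrics.csv", index=False)
    result.manifest.to_csv(out / "replicate_manifest.csv", index=False)
    result.richness.to_csv(out / "richness.csv", index=False)
    result.trends.to_csv(out / "trends.csv", index=False)
    (out / "run_config.json").write_text(
        json.dumps(
            {
                "config_hash": result.config.config_hash(),
                **{
                    k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                    for k, v in dataclasses.asdict(result.config).items()
                },
            },
            indent=2,
            default=str,
        )
    )
    logger.info("outputs written to %s", out)
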