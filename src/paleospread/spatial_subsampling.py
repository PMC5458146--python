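"""Equal-spread spatial subsampling of fossil localities.

The global per-bin MST over occupied grid cells is split into
continental-scale subtrees by iteratively deleting the longest branch until
every component's summed length is below a ceiling (13,000 km by default,
roughly continental scale).  From each retained subtree, replicate spatial
samples are grown from random seed cells along MST adjacency until their
induced subtree length reaches the target spread (3,200 km +/- 10% in the
source analysis), yielding samples of near-equal palaeogeographic spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spatial_metrics import GridCell

CellId = tuple[int, int]
Edge = tuple[CellId, CellId, float]

__all__ = [
    "RegionalSubtree",
    "SpatialSample",
    "split_global_mst",
    "remove_barrier_edges",
    "grow_spatial_sample",
    "replicate_spatial_samples",
]

DEFAULT_CEILING_KM = 13_000.0
DEFAULT_TARGET_KM = 3_200.0
DEFAULT_TOLERANCE = 0.10
DEFAULT_N_REPS = 20


@dataclass(frozen=True)
class RegionalSubtree:
    """A connected component of the split MST: one sampling region."""

    subtree_id: str
    bin: str
    cells: tuple  # GridCell, sorted by cell_id
    edges: tuple  # Edge, sorted

    @property
    def summed_mst_km(self) -> float:
        return float(sum(e[2] for e in self.edges))

    def cell_ids(self) -> list[CellId]:
        return [c.cell_id for c in self.cells]


@dataclass
class SpatialSample:
    """One accepted equal-spread subsample of grid cells."""

    replicate_id: int
    seed_cell: CellId
    cells: list  # cell_ids in growth order
    induced_mst_km: float
    target_km: float
    tolerance: float
    accepted: bool = True
    reject_reason: str | None = None
    member_cells: tuple = field(default=())  # GridCell objects


def _components(
    cell_ids: list[CellId], edges: list[Edge]
) -> list[tuple[list[CellId], list[Edge]]]:
    adj: dict[CellId, list[Edge]] = {c: [] for c in cell_ids}
    for e in edges:
        adj[e[0]].append(e)
        adj[e[1]].append(e)
    seen: set[CellId] = set()
    comps = []
    for start in sorted(cell_ids):
        if start in seen:
            continue
        stack, comp_cells, comp_edges = [start], [], set()
        seen.add(start)
        while stack:
            u = stack.pop()
            comp_cells.append(u)
            for e in adj[u]:
                comp_edges.add(e)
                v = e[1] if e[0] == u else e[0]
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append((sorted(comp_cells), sorted(comp_edges)))
    return comps


def split_global_mst(
    cells: list[GridCell],
    mst_edges: list[Edge],
    bin_name: str = "",
    ceiling_km: float = DEFAULT_CEILING_KM,
    min_km: float | None = None,
    target_km: float = DEFAULT_TARGET_KM,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[RegionalSubtree]:
    """Split a global MST into regional subtrees below the ceiling size.

    While any component's summed length is >= ``ceiling_km``, its single
    longest edge is removed (ties broken toward the lexicographically
    smallest (u, v) pair).  Components whose summed length falls below
    ``min_km`` (default ``target_km * (1 - tolerance)``, the smallest
    sampleable spread) are dropped.  Subtree ids are assigned in sorted
    order of each component's smallest cell id.
    """
    if min_km is None:
        min_km = target_km * (1.0 - tolerance)
    by_id = {c.cell_id: c for c in cells}
    work = _components(list(by_id), list(mst_edges))
    done: list[tuple[list[CellId], list[Edge]]] = []
    while work:
        comp_cells, comp_edges = work.pop(0)
        total = sum(e[2] for e in comp_edges)
        if total < ceiling_km or not comp_edges:
            done.append((comp_cells, comp_edges))
            continue
        # remove the longest edge; ties -> lexicographically smallest pair
        best_len = max(e[2] for e in comp_edges)
        longest = min(e for e in comp_edges if e[2] == best_len)
        comp_edges = [e for e in comp_edges if e != longest]
        work = _components(comp_cells, comp_edges) + work
    out = []
    kept = [
        (cc, ce) for cc, ce in done if sum(e[2] for e in ce) >= min_km
    ]
    for i, (cc, ce) in enumerate(sorted(kept, key=lambda t: t[0][0])):
        out.append(
            RegionalSubtree(
                subtree_id=f"{bin_name}-R{i}" if bin_name else f"R{i}",
                bin=bin_name,
                cells=tuple(by_id[c] for c in cc),
                edges=tuple(ce),
            )
        )
    return out


def remove_barrier_edges(
    subtrees: list[RegionalSubtree],
    barriers: list[tuple[CellId, CellId]],
    min_km: float,
) -> tuple[list[RegionalSubtree], list[str]]:
    """Remove user-listed barrier edges (e.g. land bridges crossing a
    biogeographic barrier) and re-evaluate components against ``min_km``.

    Barrier pairs matching no existing edge produce a warning string and are
    ignored.  Returns (new subtrees, warnings).
    """
    norm = {tuple(sorted((a, b))) for a, b in barriers}
    warnings = []
    matched: set[tuple[CellId, CellId]] = set()
    out: list[RegionalSubtree] = []
    for st in subtrees:
        keep_edges, cut = [], False
        for e in st.edges:
            if (e[0], e[1]) in norm:
                matched.add((e[0], e[1]))
                cut = True
            else:
                keep_edges.append(e)
        if not cut:
            out.append(st)
            continue
        by_id = {c.cell_id: c for c in st.cells}
        for k, (cc, ce) in enumerate(_components(list(by_id), keep_edges)):
            if sum(e[2] for e in ce) >= min_km:
                out.append(
                    RegionalSubtree(
                        subtree_id=f"{st.subtree_id}.{k}",
                        bin=st.bin,
                        cells=tuple(by_id[c] for c in cc),
                        edges=tuple(ce),
                    )
                )
    for a, b in sorted(norm - matched):
        warnings.append(f"barrier edge ({a}, {b}) matches no MST edge; ignored")
    return out, warnings


def grow_spatial_sample(
    subtree: RegionalSubtree,
    target_km: float = DEFAULT_TARGET_KM,
    tolerance: float = DEFAULT_TOLERANCE,
    rng: np.random.Generator | int | None = None,
    replicate_id: int = 0,
) -> SpatialSample:
    """Grow one spatial sample from a random seed cell to the target spread.

    Starting from a uniformly random cell of the subtree, the sample grows
    along MST adjacency: at each step the frontier cell joined to the current
    sample by the shortest connecting tree edge is added, so the induced
    subtree length is monotone non-decreasing.  Growth stops once the length
    reaches ``target_km``; of the states with and without the final cell, the
    one closer to the target is accepted, provided it lies within
    ``target_km * (1 +/- tolerance)`` — otherwise the sample is rejected.
    """
    rng = np.random.default_rng(rng)
    lo, hi = target_km * (1 - tolerance), target_km * (1 + tolerance)
    ids = subtree.cell_ids()
    total = subtree.summed_mst_km
    if total < lo:
        return SpatialSample(
            replicate_id, ids[0], [], 0.0, target_km, tolerance,
            accepted=False, reject_reason="subtree smaller than tolerance band",
        )
    adj: dict[CellId, list[Edge]] = {c: [] for c in ids}
    for e in subtree.edges:
        adj[e[0]].append(e)
        adj[e[1]].append(e)
    seed = ids[int(rng.integers(len(ids)))]
    in_sample = {seed}
    order = [seed]
    frontier: list[Edge] = list(adj[seed])
    length = 0.0
    prev_length = 0.0
    while length < target_km and frontier:
        # shortest frontier edge; ties toward the lexicographically smallest
        e = min(frontier, key=lambda e: (e[2], e[0], e[1]))
        frontier.remove(e)
        u, v = e[0], e[1]
        new = v if u in in_sample else u
        if new in in_sample:
            continue
        prev_length = length
        length += e[2]
        in_sample.add(new)
        order.append(new)
        for e2 in adj[new]:
            other = e2[1] if e2[0] == new else e2[0]
            if other not in in_sample:
                frontier.append(e2)
    if length < target_km:
        # exhausted the subtree before reaching the target
        if lo <= length <= hi:
            return SpatialSample(
                replicate_id, seed, order, length, target_km, tolerance
            )
        return SpatialSample(
            replicate_id, seed, order, length, target_km, tolerance,
            accepted=False, reject_reason="subtree exhausted outside band",
        )
    # choose with/without the last-added cell, whichever is closer to target
    if abs(length - target_km) <= abs(prev_length - target_km):
        chosen, chosen_len = order, length
    else:
        chosen, chosen_len = order[:-1], prev_length
    if lo <= chosen_len <= hi:
        by_id = {c.cell_id: c for c in subtree.cells}
        return SpatialSample(
            replicate_id, seed, chosen, chosen_len, target_km, tolerance,
            member_cells=tuple(by_id[c] for c in chosen),
        )
    return SpatialSample(
        replicate_id, seed, chosen, chosen_len, target_km, tolerance,
        accepted=False, reject_reason="accepted length outside tolerance band",
    )


def replicate_spatial_samples(
    subtree: RegionalSubtree,
    n_reps: int = DEFAULT_N_REPS,
    target_km: float = DEFAULT_TARGET_KM,
    tolerance: float = DEFAULT_TOLERANCE,
    master_seed: int | np.random.SeedSequence = 0,
    retry_cap: int = 100,
) -> list[SpatialSample]:
    """Draw ``n_reps`` replicate equal-spread samples from one subtree.

    Each replicate uses an independent random stream derived from
    ``master_seed`` (reproducible bit-for-bit for a given seed).  A rejected
    draw is retried up to ``retry_cap`` times; if a replicate never accepts,
    its last rejection is returned so callers can report the subtree as
    unsampleable rather than fail.
    """
    ss = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    streams = ss.spawn(n_reps)
    out = []
    for rep, child in enumerate(streams):
        rng = np.random.default_rng(child)
        sample = None
        for _ in range(retry_cap):
            sample = grow_spatial_sample(
                subtree, target_km, tolerance, rng, replicate_id=rep
            )
            if sample.accepted:
                break
        out.append(sample)
    return out
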