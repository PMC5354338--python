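"""Structural connectivity: area graphs and sparse synapse sets.

Two architectures are compared.  The monkey architecture (MA) links the six
perisylvian areas A1-AB-PB-PF-PM-M1 by reciprocal next-neighbour projections
only; the human architecture (HA) adds reciprocal "jumping" projections that
skip one intermediate area (A1-PB, AB-PF, PB-PM, PF-M1), shortening the
synaptic path from auditory input to articulatory output from five steps to
three.  Within every area, and for every between-area projection, individual
excitatory links are drawn at random with a Gaussian distance profile clipped
to a 19 x 19 neighbourhood, producing sparse, patchy, topographic wiring.
Each excitatory cell also has a companion inhibitory cell that pools
excitatory output from the surrounding 5 x 5 patch and feeds back onto its
own column only.
"""

from __future__ import annotations

import copy
import dataclasses
import json

import numpy as np
import scipy.sparse

from .stimuli import WordPattern, generate_patterns

AREAS: tuple[str, ...] = ("A1", "AB", "PB", "PF", "PM", "M1")

NEXT_NEIGHBOR_PAIRS = tuple(zip(AREAS[:-1], AREAS[1:]))
JUMPING_PAIRS = (("A1", "PB"), ("AB", "PF"), ("PB", "PM"), ("PF", "M1"))

NEIGHBORHOOD_E = 19   # excitatory projection window (cells, odd)
NEIGHBORHOOD_I = 5    # inhibitory pooling window

#: defaults for the Gaussian link-probability profile; chosen so that the
#: expected acceptance rate over the 19 x 19 window is ~0.15 (~54 afferents
#: per projection), see docs/methods.md.
SIGMA_DEFAULT = 4.5
P0_DEFAULT = 0.457


@dataclasses.dataclass(frozen=True)
class AreaGraph:
    """Ordered area list plus the set of directed between-area projections."""

    areas: tuple[str, ...]
    projections: frozenset  # of (src, dst, kind); kind in {next_neighbor, jumping}

    @staticmethod
    def _reciprocal(pairs, kind):
        out = set()
        for a, b in pairs:
            out.add((a, b, kind))
            out.add((b, a, kind))
        return out

    @classmethod
    def monkey(cls) -> "AreaGraph":
        return cls(AREAS, frozenset(cls._reciprocal(NEXT_NEIGHBOR_PAIRS,
                                                    "next_neighbor")))

    @classmethod
    def human(cls) -> "AreaGraph":
        links = cls._reciprocal(NEXT_NEIGHBOR_PAIRS, "next_neighbor")
        links |= cls._reciprocal(JUMPING_PAIRS, "jumping")
        return cls(AREAS, frozenset(links))

    @classmethod
    def chain(cls, areas) -> "AreaGraph":
        """Next-neighbour chain over an arbitrary area list (for toy models)."""
        areas = tuple(areas)
        return cls(areas, frozenset(cls._reciprocal(zip(areas[:-1], areas[1:]),
                                                    "next_neighbor")))

    @property
    def directed_links(self) -> set[tuple[str, str]]:
        return {(s, d) for s, d, _ in self.projections}

    def jumping_links(self) -> set[tuple[str, str]]:
        return {(s, d) for s, d, k in self.projections if k == "jumping"}

    def degree(self, area: str) -> int:
        """Number of projection pairs the area participates in."""
        return sum(1 for s, d, _ in self.projections if s == area)

    def path_length(self, src: str, dst: str) -> int:
        """Minimal number of between-area synaptic steps from src to dst."""
        frontier, dist, seen = [src], 0, {src}
        adj: dict[str, list[str]] = {}
        for s, d, _ in self.projections:
            adj.setdefault(s, []).append(d)
        while frontier:
            if dst in frontier:
                return dist
            frontier = [d for s in frontier for d in adj.get(s, [])
                        if d not in seen]
            seen.update(frontier)
            dist += 1
        raise ValueError(f"no path from {src} to {dst}")


def connection_probability(dx, dy, sigma: float = SIGMA_DEFAULT,
                           p0: float = P0_DEFAULT,
                           n: int = NEIGHBORHOOD_E):
    """Gaussian fall-off with cell offset, clipped to zero outside the
    ``n`` x ``n`` neighbourhood.  Depends on Euclidean distance only."""
    if n % 2 != 1:
        raise ValueError("window size n must be odd")
    if not (0 <= p0 <= 1):
        raise ValueError("p0 must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    half = (n - 1) // 2
    p = p0 * np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
    inside = (np.abs(dx) <= half) & (np.abs(dy) <= half)
    return np.where(inside, p, 0.0)


class SynapseSet:
    """Sparse directed excitatory links over all areas.

    ``pre``/``post``/``w`` are parallel coordinate arrays sorted by source
    cell (flat area-major indices); ``pindptr`` delimits the out-links of
    each source, which is the layout the propagation kernel streams through.
    A post-major (afferent) view for the plasticity pass is built lazily.
    Inhibitory wiring is fixed and rule-generated (5 x 5 pooling, own-column
    feedback); its gains live in :class:`~perisylvian.params.ModelParams`.
    """

    def __init__(self, side, areas, pindptr, pre, post, w, meta=None):
        self.side = int(side)
        self.areas = tuple(areas)
        self.pindptr = np.asarray(pindptr, dtype=np.int64)
        self.pre = np.asarray(pre, dtype=np.int32)
        self.post = np.asarray(post, dtype=np.int32)
        self.w = np.asarray(w, dtype=np.float64)
        self.meta = dict(meta or {})
        if len(self.pindptr) != self.n_cells + 1:
            raise ValueError("pindptr length does not match cell count")

    # --- basic geometry ---------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def area_cells(self) -> int:
        return self.side * self.side

    @property
    def n_cells(self) -> int:
        return self.n_areas * self.area_cells

    @property
    def n_links(self) -> int:
        return len(self.w)

    def area_of(self, cell):
        return np.asarray(cell) // self.area_cells

    # --- views --------------------------------------------------------------
    def csr_matrix(self) -> scipy.sparse.csr_matrix:
        """Afferent-weight matrix W with W[post, pre] = weight."""
        return scipy.sparse.coo_matrix(
            (self.w, (self.post.astype(np.int64), self.pre.astype(np.int64))),
            shape=(self.n_cells, self.n_cells),
        ).tocsr()

    def links_by_projection(self) -> dict[tuple[str, str], int]:
        """Realised link count per (source area, target area)."""
        pa = self.area_of(self.pre)
        qa = self.area_of(self.post)
        counts: dict[tuple[str, str], int] = {}
        for s in range(self.n_areas):
            for d in range(self.n_areas):
                n = int(np.sum((pa == s) & (qa == d)))
                if n:
                    counts[(self.areas[s], self.areas[d])] = n
        return counts

    def afferent_arrays(self):
        """Post-major companion index for the plasticity pass: (indptr over
        targets, source cell per link, position into ``w`` per link).  Built
        lazily; the link structure is static, only ``w`` values change."""
        if not hasattr(self, "_afferent"):
            order = np.argsort(self.post, kind="stable")
            indptr = np.zeros(self.n_cells + 1, dtype=np.int64)
            np.add.at(indptr, self.post.astype(np.int64) + 1, 1)
            indptr = np.cumsum(indptr)
            self._afferent = (indptr, self.pre[order].astype(np.int32),
                              order.astype(np.int32))
        return self._afferent

    def copy(self) -> "SynapseSet":
        return SynapseSet(self.side, self.areas, self.pindptr.copy(),
                          self.pre.copy(), self.post.copy(), self.w.copy(),
                          copy.deepcopy(self.meta))

    def without_projections(self, pairs) -> "SynapseSet":
        """New SynapseSet with every link whose (src area, dst area) is in
        ``pairs`` removed; surviving links and weights are untouched."""
        pairs = set(pairs)
        keep = np.ones(self.n_links, dtype=bool)
        pa = self.area_of(self.pre)
        qa = self.area_of(self.post)
        for s, d in pairs:
            si, di = self.areas.index(s), self.areas.index(d)
            keep &= ~((pa == si) & (qa == di))
        pre = self.pre[keep]      # mask keeps the pre-major ordering
        post = self.post[keep]
        w = self.w[keep]
        pindptr = np.zeros(self.n_cells + 1, dtype=np.int64)
        np.add.at(pindptr, pre.astype(np.int64) + 1, 1)
        pindptr = np.cumsum(pindptr)
        meta = dict(self.meta, removed_projections=sorted(pairs))
        return SynapseSet(self.side, self.areas, pindptr, pre, post, w, meta)

    # --- serialisation ----------------------------------------------------
    def save(self, path) -> None:
        np.savez_compressed(path, side=self.side, pindptr=self.pindptr,
                            pre=self.pre, post=self.post, w=self.w,
                            areas=np.array(self.areas))
        with open(str(path) + ".json", "w") as fh:
            json.dump(self.meta, fh, default=str)

    @classmethod
    def load(cls, path) -> "SynapseSet":
        z = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        try:
            with open(str(path).removesuffix(".npz") + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {}
        return cls(int(z["side"]), tuple(z["areas"]), z["pindptr"], z["pre"],
                   z["post"], z["w"], meta)


def inhibitory_links(side: int, window: int = NEIGHBORHOOD_I):
    """Yield (e_cell, i_cell) pooling links of one area, plus the feedback
    (i_cell, e_cell) own-column links, as two lists of index pairs.

    The wiring is deterministic: inhibitory cell (r, c) receives from every
    excitatory cell in the clipped ``window`` x ``window`` patch around
    (r, c) and projects back to excitatory cell (r, c) only.
    """
    half = window // 2
    pool, feedback = [], []
    for r in range(side):
        for c in range(side):
            i_cell = r * side + c
            feedback.append((i_cell, i_cell))
            for dr in range(-half, half + 1):
                rr = r + dr
                if not (0 <= rr < side):
                    continue
                for dc in range(-half, half + 1):
                    cc = c + dc
                    if 0 <= cc < side:
                        pool.append((rr * side + cc, i_cell))
    return pool, feedback


def build_synapses(
    graph: AreaGraph,
    sigma: float = SIGMA_DEFAULT,
    p0: float = P0_DEFAULT,
    rng: np.random.Generator | None = None,
    side: int = 25,
    w_init_max: float = 0.1,
) -> SynapseSet:
    """Realise the excitatory links of ``graph`` (within-area links for every
    area plus every directed between-area projection).

    Every candidate (pre, post) pair whose grid offset lies in the 19 x 19
    window is accepted independently with :func:`connection_probability`;
    accepted weights are uniform on [0, ``w_init_max``].  Between-area
    projections are topographic: cell (r, c) of the source area targets the
    window centred on (r, c) of the destination area.  Within-area self links
    are excluded.  Deterministic given ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = NEIGHBORHOOD_E
    half = (n - 1) // 2
    offs = np.arange(-half, half + 1)
    dr = np.repeat(offs, n)
    dc = np.tile(offs, n)
    prob = np.asarray(connection_probability(dr, dc, sigma, p0, n))

    area_cells = side * side
    areas = graph.areas
    idx = {a: i for i, a in enumerate(areas)}

    # candidate geometry, shared by every projection
    r0 = np.repeat(np.arange(side), side)
    c0 = np.tile(np.arange(side), side)
    rr = r0[:, None] + dr[None, :]          # (cells, n*n)
    cc = c0[:, None] + dc[None, :]
    valid = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
    pre_local = np.where(valid, rr * side + cc, 0)

    projections = [(a, a, "within") for a in areas]
    projections += sorted((s, d, k) for s, d, k in graph.projections)

    posts, pres, ws = [], [], []
    for src, dst, kind in projections:
        accept = (rng.random(pre_local.shape) < prob[None, :]) & valid
        weights = rng.uniform(0.0, w_init_max, size=pre_local.shape)
        if kind == "within":
            accept &= ((dr != 0) | (dc != 0))[None, :]  # no self links
        sel_post, sel_off = np.nonzero(accept)
        posts.append(sel_post + idx[dst] * area_cells)
        pres.append(pre_local[sel_post, sel_off] + idx[src] * area_cells)
        ws.append(weights[sel_post, sel_off])

    post = np.concatenate(posts).astype(np.int64)
    pre = np.concatenate(pres).astype(np.int64)
    w = np.concatenate(ws)
    order = np.argsort(pre, kind="stable")
    post, pre, w = post[order], pre[order], w[order]
    n_cells = len(areas) * area_cells
    pindptr = np.zeros(n_cells + 1, dtype=np.int64)
    np.add.at(pindptr, pre + 1, 1)
    pindptr = np.cumsum(pindptr)
    meta = {"sigma": sigma, "p0": p0, "side": side, "w_init_max": w_init_max}
    return SynapseSet(side, areas, pindptr, pre, post, w, meta)


@dataclasses.dataclass
class NetworkInstance:
    """One structural network: architecture tag, graph, synapses, patterns.

    Dynamic state is owned by the protocol layer; an instance is the immutable
    'anatomy plus curriculum' shared bookkeeping of one simulation subject.
    """

    tag: str                    # "HA" or "MA"
    graph: AreaGraph
    synapses: SynapseSet
    patterns: list[WordPattern]
    instance_seed: int

    @property
    def side(self) -> int:
        return self.synapses.side

    @property
    def n_cells(self) -> int:
        return self.synapses.n_cells


def instantiate_pair(
    seed: int,
    sigma: float = SIGMA_DEFAULT,
    p0: float = P0_DEFAULT,
    side: int = 25,
    n_patterns: int = 14,
    cells_per_pattern: int = 17,
) -> tuple[NetworkInstance, NetworkInstance]:
    """Build one (HA, MA) twin pair.

    The HA network is initialised first (random links, random weights, random
    word patterns); the MA member is a copy with every jumping-projection link
    deleted.  All surviving links, weights and the pattern set are identical
    between the two members, so the architectures differ only in long-distance
    connectivity.
    """
    rng = np.random.default_rng(seed)
    ha_graph = AreaGraph.human()
    ma_graph = AreaGraph.monkey()
    syn_ha = build_synapses(ha_graph, sigma, p0, rng, side=side)
    syn_ha.meta.update(architecture="HA", seed=seed)
    patterns = generate_patterns(n_patterns, cells_per_pattern, rng,
                                 area_cells=side * side)
    syn_ma = syn_ha.without_projections(ha_graph.jumping_links())
    syn_ma.meta.update(architecture="MA", seed=seed)
    ha = NetworkInstance("HA", ha_graph, syn_ha, patterns, seed)
    ma = NetworkInstance("MA", ma_graph, syn_ma, patterns, seed)
    return ha, ma
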