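"""Species state: occupancy, traits, demes and divergence.

Allopatric speciation with a divergence threshold: a species' occupied
cells are partitioned each step into geographic clusters (connected
components under the reachability radius). Lineage "demes" — historical
cluster fragments — carry a symmetric nonnegative divergence ledger.
Isolation adds 1 per step between demes in different clusters; secondary
contact heals 1 per step (floor 0), and demes whose divergence returns
to zero while co-clustered merge back. When every deme of a cluster has
accumulated divergence >= τ against all demes outside the cluster, the
cluster buds off as a new species, inheriting its cells, abundances and
trait values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


@dataclass
class Species:
    sid: int
    parent: int | None
    origin_age: float
    origin_step: int
    n: dict[int, float] = field(default_factory=dict)  # flat cell -> abundance
    t_opt: dict[int, float] = field(default_factory=dict)
    p_opt: dict[int, float] = field(default_factory=dict)
    deme: dict[int, int] = field(default_factory=dict)  # flat cell -> deme id
    div: dict[tuple[int, int], float] = field(default_factory=dict)
    next_deme: int = 1
    extinct_age: float | None = None
    extinct_step: int | None = None
    arrivals: set[int] = field(default_factory=set)
    last_cells: tuple[int, ...] = ()  # occupancy snapshot before ecology

    @property
    def extant(self) -> bool:
        return self.extinct_age is None

    def cells(self) -> list[int]:
        return sorted(self.n)

    def remove_cell(self, cell: int) -> None:
        self.n.pop(cell, None)
        self.t_opt.pop(cell, None)
        self.p_opt.pop(cell, None)
        d = self.deme.pop(cell, None)
        if d is not None and d not in self.deme.values():
            self.div = {k: v for k, v in self.div.items() if d not in k}

    def demes_present(self) -> list[int]:
        return sorted(set(self.deme.values()))

    def divergence(self, a: int, b: int) -> float:
        return self.div.get(_key(a, b), 0.0) if a != b else 0.0

    def _set_div(self, a: int, b: int, v: float) -> None:
        k = _key(a, b)
        if v <= 0:
            self.div.pop(k, None)
        else:
            self.div[k] = v


def refine_demes(species: Species, labels: dict[int, int]) -> None:
    """Split demes whose cells now span several geographic clusters.

    The largest fragment (tie: lowest cluster label) keeps the deme id;
    the others become new demes inheriting the parent's divergences to
    every other deme, with zero divergence between siblings.
    """
    by_deme: dict[int, dict[int, list[int]]] = {}
    for cell, d in species.deme.items():
        by_deme.setdefault(d, {}).setdefault(labels[cell], []).append(cell)
    for d, groups in sorted(by_deme.items()):
        if len(groups) <= 1:
            continue
        ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        others = [e for e in species.demes_present() if e != d]
        new_ids = []
        for _, cells in ordered[1:]:
            nd = species.next_deme
            species.next_deme += 1
            new_ids.append(nd)
            for c in cells:
                species.deme[c] = nd
            for e in others:
                species._set_div(nd, e, species.divergence(d, e))
        # siblings (including the id-keeping fragment) start at 0
        for i, x in enumerate([d] + new_ids):
            for y in ([d] + new_ids)[i + 1:]:
                species._set_div(x, y, 0.0)


def update_divergence(species: Species, labels: dict[int, int]) -> None:
    """+1 per step between demes in different clusters; -1 (floor 0) on
    secondary contact; fully healed co-clustered demes merge."""
    deme_cluster: dict[int, int] = {}
    for cell, d in species.deme.items():
        deme_cluster[d] = labels[cell]
    demes = sorted(deme_cluster)
    to_merge: list[tuple[int, int]] = []
    for i, a in enumerate(demes):
        for b in demes[i + 1:]:
            same = deme_cluster[a] == deme_cluster[b]
            v = species.divergence(a, b)
            if same:
                v = max(0.0, v - 1.0)
                species._set_div(a, b, v)
                if v == 0.0:
                    to_merge.append((a, b))
            else:
                species._set_div(a, b, v + 1.0)
    # union-find style merge of fully-healed co-clustered demes
    parent = {d: d for d in demes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in to_merge:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for d in demes:
        groups.setdefault(find(d), []).append(d)
    for root, members in groups.items():
        if len(members) == 1:
            continue
        for m in members:
            if m == root:
                continue
            for cell, d in list(species.deme.items()):
                if d == m:
                    species.deme[cell] = root
        # divergence of the merged deme to outsiders: maximum over members
        outsiders = [e for e in demes if find(e) != root]
        for e in outsiders:
            v = max(species.divergence(m, e) for m in members)
            species._set_div(root, e, v)
        for i, x in enumerate(members):
            for y in members[i + 1:]:
                species.div.pop(_key(x, y), None)


def speciating_clusters(
    species: Species, labels: dict[int, int], tau: float
) -> list[int]:
    """Cluster labels whose demes all diverged >= τ from every deme
    outside the cluster. The cluster holding the most cells (tie: lowest
    label) is retained by the parent and never buds."""
    cluster_cells: dict[int, int] = {}
    cluster_demes: dict[int, set[int]] = {}
    for cell, lab in labels.items():
        cluster_cells[lab] = cluster_cells.get(lab, 0) + 1
        cluster_demes.setdefault(lab, set()).add(species.deme[cell])
    if len(cluster_cells) < 2:
        return []
    keep = min(cluster_cells, key=lambda c: (-cluster_cells[c], c))
    out = []
    for lab in sorted(cluster_demes):
        if lab == keep:
            continue
        inside = cluster_demes[lab]
        outside = set().union(
            *(v for k, v in cluster_demes.items() if k != lab)
        )
        if all(
            species.divergence(a, b) >= tau for a in inside for b in outside
        ):
            out.append(lab)
    return out


def bud_species(
    species: Species,
    labels: dict[int, int],
    lab: int,
    new_sid: int,
    age: float,
    step: int,
) -> Species:
    """Detach cluster `lab` from `species` into a new species."""
    cells = sorted(c for c, l in labels.items() if l == lab)
    child = Species(sid=new_sid, parent=species.sid, origin_age=age,
                    origin_step=step)
    moved_demes = sorted({species.deme[c] for c in cells})
    remap = {d: i + 1 for i, d in enumerate(moved_demes)}
    child.next_deme = len(moved_demes) + 1
    for c in cells:
        child.n[c] = species.n[c]
        child.t_opt[c] = species.t_opt[c]
        child.p_opt[c] = species.p_opt[c]
        child.deme[c] = remap[species.deme[c]]
        if c in species.arrivals:
            species.arrivals.discard(c)
            child.arrivals.add(c)
    for i, a in enumerate(moved_demes):
        for b in moved_demes[i + 1:]:
            v = species.divergence(a, b)
            if v > 0:
                child.div[_key(remap[a], remap[b])] = v
    for c in cells:
        species.n.pop(c)
        species.t_opt.pop(c)
        species.p_opt.pop(c)
        species.deme.pop(c)
    species.div = {
        k: v
        for k, v in species.div.items()
        if k[0] not in moved_demes and k[1] not in moved_demes
    }
    return child


def evolve_traits(
    species: Species,
    labels: dict[int, int],
    t_site: dict[int, float],
    sigma: float,
    rng: np.random.Generator,
) -> None:
    """Directed bounded trait step toward cluster-local conditions.

    Per cluster: T̄s = mean normalized site temperature over the
    cluster's cells; one half-normal step |N(0, σ²)| moves the cluster's
    thermal optimum toward T̄s without overshooting. σ=0 or a cluster
    already at its local mean leaves the optimum unchanged.
    """
    clusters: dict[int, list[int]] = {}
    for cell, lab in labels.items():
        clusters.setdefault(lab, []).append(cell)
    for lab in sorted(clusters):
        cells = sorted(clusters[lab])
        t_bar_i = float(np.mean([species.t_opt[c] for c in cells]))
        t_bar_s = float(np.mean([t_site[c] for c in cells]))
        step = abs(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
        gap = t_bar_s - t_bar_i
        if gap == 0 or step == 0:
            continue
        delta = np.sign(gap) * min(step, abs(gap))
        for c in cells:
            species.t_opt[c] += delta
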