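"""Structured-coalescent simulation engine.

Implements the exact single-locus structured coalescent: within every open
deme each lineage pair coalesces at rate ``1/(2*N_d)`` per generation, and
lineages migrate (backward in time) at the per-generation probabilities of
the scenario's migration matrix.  Merge events move lineages and resize the
receiving deme at exact event times.  For unlinked single-SNP loci this
coincides with the sequentially Markovian approximations used by
simulation-based SFS methods, so no recombination machinery is needed.

The hot loops are numba-compiled; all randomness flows through explicit
seeds, and a given seed reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .scenarios import DemographicScenario
from .sfs import FoldedMSFS, fold_tensor


@njit(cache=True)
def _simulate_one(sizes0, mig0, ev_time, ev_src, ev_dst, ev_resize, n_per_deme,
                  strides, parent, ntime, node_deme, counts, birth, br_cell, br_w, br_node):
    """Simulate one genealogy; fills the preallocated node/branch arrays.

    Returns (status, n_nodes, n_branch_records); status 1 means the
    configuration cannot coalesce (disconnected demes with no events left).
    Branch records hold, for every non-root lineage, the flat (unfolded) SFS
    cell determined by its per-deme descendant leaf counts and its length in
    generations; a mutation on the branch yields a SNP in that cell.
    """
    n_demes = sizes0.shape[0]
    n_tot = 0
    for d in range(n_demes):
        n_tot += n_per_deme[d]
    lin_node = np.empty(n_tot, np.int64)
    lin_deme = np.empty(n_tot, np.int64)
    node = 0
    k = 0
    for d in range(n_demes):
        for _ in range(n_per_deme[d]):
            parent[node] = -1
            ntime[node] = 0.0
            birth[node] = 0.0
            for dd in range(n_demes):
                counts[node, dd] = 0
            counts[node, d] = 1
            node_deme[node] = d
            lin_node[k] = node
            lin_deme[k] = d
            node += 1
            k += 1
    sizes = sizes0.copy()
    migr = mig0.copy()
    mig_row = np.empty(n_demes)
    for d in range(n_demes):
        s = 0.0
        for j in range(n_demes):
            s += migr[d, j]
        mig_row[d] = s
    t = 0.0
    iev = 0
    nb = 0
    n_ev = ev_time.shape[0]
    kd = np.empty(n_demes, np.int64)
    while k > 1:
        for d in range(n_demes):
            kd[d] = 0
        for i in range(k):
            kd[lin_deme[i]] += 1
        total_rate = 0.0
        for d in range(n_demes):
            if kd[d] > 1:
                total_rate += kd[d] * (kd[d] - 1) / 2.0 / (2.0 * sizes[d])
            total_rate += kd[d] * mig_row[d]
        if total_rate > 0.0:
            dt = np.random.exponential(1.0 / total_rate)
        else:
            dt = np.inf
        if iev < n_ev and (total_rate == 0.0 or t + dt >= ev_time[iev]):
            t = ev_time[iev]
            src = ev_src[iev]
            dst = ev_dst[iev]
            for i in range(k):
                if lin_deme[i] == src:
                    lin_deme[i] = dst
            sizes[dst] = sizes[dst] * ev_resize[iev]
            for j in range(n_demes):
                migr[src, j] = 0.0
                migr[j, src] = 0.0
            for d in range(n_demes):
                s = 0.0
                for j in range(n_demes):
                    s += migr[d, j]
                mig_row[d] = s
            iev += 1
            continue
        if total_rate == 0.0:
            return 1, node, nb
        t += dt
        u = np.random.random() * total_rate
        for d in range(n_demes):
            c_rate = 0.0
            if kd[d] > 1:
                c_rate = kd[d] * (kd[d] - 1) / 2.0 / (2.0 * sizes[d])
            if u < c_rate:
                a = int(np.random.random() * kd[d])
                if a >= kd[d]:
                    a = kd[d] - 1
                b = int(np.random.random() * (kd[d] - 1))
                if b >= kd[d] - 1:
                    b = kd[d] - 2
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                c = 0
                for i in range(k):
                    if lin_deme[i] == d:
                        if c == a:
                            ia = i
                        if c == b:
                            ib = i
                        c += 1
                c1 = lin_node[ia]
                c2 = lin_node[ib]
                v = node
                node += 1
                parent[c1] = v
                parent[c2] = v
                parent[v] = -1
                ntime[v] = t
                birth[v] = t
                node_deme[v] = d
                cell1 = 0
                cell2 = 0
                for dd in range(n_demes):
                    counts[v, dd] = counts[c1, dd] + counts[c2, dd]
                    cell1 += counts[c1, dd] * strides[dd]
                    cell2 += counts[c2, dd] * strides[dd]
                br_cell[nb] = cell1
                br_w[nb] = t - birth[c1]
                br_node[nb] = c1
                nb += 1
                br_cell[nb] = cell2
                br_w[nb] = t - birth[c2]
                br_node[nb] = c2
                nb += 1
                lin_node[ia] = v
                lin_deme[ia] = d
                lin_node[ib] = lin_node[k - 1]
                lin_deme[ib] = lin_deme[k - 1]
                k -= 1
                break
            u -= c_rate
            m_rate = kd[d] * mig_row[d]
            if u < m_rate:
                a = int(np.random.random() * kd[d])
                if a >= kd[d]:
                    a = kd[d] - 1
                ia = -1
                c = 0
                for i in range(k):
                    if lin_deme[i] == d:
                        if c == a:
                            ia = i
                            break
                        c += 1
                w = np.random.random() * mig_row[d]
                jj = -1
                for j in range(n_demes):
                    if migr[d, j] > 0.0:
                        jj = j
                        if w < migr[d, j]:
                            break
                        w -= migr[d, j]
                lin_deme[ia] = jj
                break
            u -= m_rate
    return 0, node, nb


@njit(cache=True)
def _sfs_batch(seed, n_sim, sizes0, mig0, ev_time, ev_src, ev_dst, ev_resize,
               n_per_deme, strides, n_cells):
    """Accumulate branch-length SFS weights over ``n_sim`` genealogies and
    draw one mutation cell per genealogy (branch picked proportionally to
    its length).  Returns (weights, sampled cells, status)."""
    np.random.seed(seed)
    sfs = np.zeros(n_cells)
    cells = np.empty(n_sim, np.int64)
    n_tot = 0
    for d in range(n_per_deme.shape[0]):
        n_tot += n_per_deme[d]
    max_nodes = 2 * n_tot - 1
    parent = np.empty(max_nodes, np.int64)
    ntime = np.empty(max_nodes)
    node_deme = np.empty(max_nodes, np.int64)
    counts = np.empty((max_nodes, n_per_deme.shape[0]), np.int64)
    birth = np.empty(max_nodes)
    br_cell = np.empty(max_nodes, np.int64)
    br_w = np.empty(max_nodes)
    br_node = np.empty(max_nodes, np.int64)
    for s in range(n_sim):
        status, _, nb = _simulate_one(
            sizes0, mig0, ev_time, ev_src, ev_dst, ev_resize, n_per_deme,
            strides, parent, ntime, node_deme, counts, birth, br_cell, br_w, br_node)
        if status != 0:
            return sfs, cells, status
        tot = 0.0
        for i in range(nb):
            tot += br_w[i]
        u = np.random.random() * tot
        pick = nb - 1
        acc = 0.0
        for i in range(nb):
            acc += br_w[i]
            if u < acc:
                pick = i
                break
        cells[s] = br_cell[pick]
        for i in range(nb):
            sfs[br_cell[i]] += br_w[i]
    return sfs, cells, 0


@njit(cache=True)
def _tree_once(seed, sizes0, mig0, ev_time, ev_src, ev_dst, ev_resize,
               n_per_deme, strides):
    """Simulate a single genealogy; returns (status, parent, times, branch
    cells, branch weights, n_branch)."""
    np.random.seed(seed)
    n_tot = 0
    for d in range(n_per_deme.shape[0]):
        n_tot += n_per_deme[d]
    max_nodes = 2 * n_tot - 1
    parent = np.empty(max_nodes, np.int64)
    ntime = np.empty(max_nodes)
    node_deme = np.empty(max_nodes, np.int64)
    counts = np.empty((max_nodes, n_per_deme.shape[0]), np.int64)
    birth = np.empty(max_nodes)
    br_cell = np.empty(max_nodes, np.int64)
    br_w = np.empty(max_nodes)
    br_node = np.empty(max_nodes, np.int64)
    status, _, nb = _simulate_one(
        sizes0, mig0, ev_time, ev_src, ev_dst, ev_resize, n_per_deme,
        strides, parent, ntime, node_deme, counts, birth, br_cell, br_w, br_node)
    return status, parent, ntime, br_cell, br_w, br_node, nb


def _lineage_counts(scenario: DemographicScenario, sample_config: dict[str, int]) -> np.ndarray:
    n = np.zeros(len(scenario.demes), dtype=np.int64)
    for d, nd in sample_config.items():
        if d not in scenario.demes:
            raise ValueError(f"sampled deme {d!r} not in scenario")
        if nd < 0:
            raise ValueError("negative sample size")
        n[scenario.demes.index(d)] = 2 * nd
    if n.sum() < 2:
        raise ValueError("need at least two sampled lineages")
    return n


def _strides(n_per_deme: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    shape = tuple(int(m) + 1 for m in n_per_deme)
    strides = np.empty(len(shape), dtype=np.int64)
    acc = 1
    for d in range(len(shape) - 1, -1, -1):
        strides[d] = acc
        acc *= shape[d]
    return strides, shape


@dataclass
class Genealogy:
    """An ultrametric coalescent genealogy of ``n_leaves`` sampled lineages.

    Nodes ``0..n_leaves-1`` are leaves (grouped by deme in scenario deme
    order); internal nodes follow in coalescence order; the last node is the
    root.  Times are in generations before present.
    """

    parent: np.ndarray
    time: np.ndarray
    leaf_demes: np.ndarray
    n_leaves: int

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    @property
    def total_branch_length(self) -> float:
        nodes = np.arange(self.n_nodes - 1)
        return float(np.sum(self.time[self.parent[nodes]] - self.time[nodes]))

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        nodes = np.arange(self.n_nodes - 1)
        return self.time[self.parent[nodes]] - self.time[nodes]

    def leaves_below(self, node: int) -> np.ndarray:
        """Leaf indices in the subtree rooted at ``node``."""
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            children[self.parent[v]].append(v)
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            else:
                stack.extend(children[v])
        return np.array(sorted(out), dtype=int)


def simulate_genealogy(
    scenario: DemographicScenario, sample_config: dict[str, int], seed: int
) -> Genealogy:
    """Simulate one genealogy of ``sample_config`` (diploids per deme) under
    the scenario.  Raises if the configuration cannot fully coalesce."""
    n_per_deme = _lineage_counts(scenario, sample_config)
    strides, _ = _strides(n_per_deme)
    sizes, mig, ev_t, ev_s, ev_d, ev_r = scenario.arrays()
    status, parent, ntime, _, _, _, _ = _tree_once(
        int(seed) % 2**31, sizes, mig, ev_t, ev_s, ev_d, ev_r, n_per_deme, strides)
    if status != 0:
        raise ValueError("non-coalescing configuration: isolated demes with no merge events")
    leaf_demes = np.repeat(np.arange(len(scenario.demes)), n_per_deme)
    return Genealogy(parent=parent, time=ntime, leaf_demes=leaf_demes,
                     n_leaves=int(n_per_deme.sum()))


def expected_sfs(
    scenario: DemographicScenario,
    sample_config: dict[str, int],
    n_sim: int,
    seed: int,
) -> FoldedMSFS:
    """Monte-Carlo expected folded mSFS under the scenario.

    Averages branch-length-weighted mutation placement over ``n_sim``
    genealogies; entries are proportions summing to 1 over unmasked
    (polymorphic, canonical) cells.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    n_per_deme = _lineage_counts(scenario, sample_config)
    strides, shape = _strides(n_per_deme)
    sizes, mig, ev_t, ev_s, ev_d, ev_r = scenario.arrays()
    weights, _, status = _sfs_batch(
        int(seed) % 2**31, int(n_sim), sizes, mig, ev_t, ev_s, ev_d, ev_r,
        n_per_deme, strides, int(np.prod(shape)))
    if status != 0:
        raise ValueError("non-coalescing configuration: isolated demes with no merge events")
    folded = fold_tensor(weights.reshape(shape))
    sampled_demes = [d for d, m in zip(scenario.demes, n_per_deme) if m > 0]
    if len(sampled_demes) != len(scenario.demes):
        # drop unsampled axes (they are singleton dimensions)
        keep = tuple(i for i, m in enumerate(n_per_deme) if m > 0)
        folded = folded.reshape([shape[i] for i in keep])
        n_per_deme = n_per_deme[list(keep)]
    spec = FoldedMSFS(
        values=folded,
        regions=sampled_demes,
        sample_sizes=[int(m) for m in n_per_deme],
        kind="counts",
        meta={"n_sim": int(n_sim), "seed": int(seed)},
    )
    return spec.normalised()


def sample_sfs_counts(
    scenario: DemographicScenario,
    sample_config: dict[str, int],
    n_loci: int,
    seed: int,
) -> FoldedMSFS:
    """Simulate an observed folded mSFS of ``n_loci`` unlinked SNPs: one
    genealogy per locus, one mutation placed proportionally to branch length
    (every such site is polymorphic in the total sample)."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    n_per_deme = _lineage_counts(scenario, sample_config)
    strides, shape = _strides(n_per_deme)
    sizes, mig, ev_t, ev_s, ev_d, ev_r = scenario.arrays()
    _, cells, status = _sfs_batch(
        int(seed) % 2**31, int(n_loci), sizes, mig, ev_t, ev_s, ev_d, ev_r,
        n_per_deme, strides, int(np.prod(shape)))
    if status != 0:
        raise ValueError("non-coalescing configuration: isolated demes with no merge events")
    counts = np.bincount(cells, minlength=int(np.prod(shape))).astype(float)
    folded = fold_tensor(counts.reshape(shape))
    sampled_demes = [d for d, m in zip(scenario.demes, n_per_deme) if m > 0]
    if len(sampled_demes) != len(scenario.demes):
        keep = tuple(i for i, m in enumerate(n_per_deme) if m > 0)
        folded = folded.reshape([shape[i] for i in keep])
        n_per_deme = n_per_deme[list(keep)]
    return FoldedMSFS(
        values=folded,
        regions=sampled_demes,
        sample_sizes=[int(m) for m in n_per_deme],
        kind="counts",
        meta={"n_loci": int(n_loci), "seed": int(seed)},
    )
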