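"""Folded multidimensional site-frequency spectra (mSFS).

The joint SFS over R regions is a tensor of shape ``prod(2*n_r + 1)`` indexed
by per-region derived-allele counts.  Because ancestral states are unknown the
spectrum is *folded*: each cell is combined with its complement (the cell
obtained by swapping allele labels in every region) and indexed by the global
minor allele.  Cells that are invisible to polymorphism (global count 0 or
maximal) are masked and excluded from totals and likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .datamodel import GenotypeMatrix, PopulationMap


def _complement_indices(shape: tuple[int, ...]) -> np.ndarray:
    """Flat index of the allele-label-swapped cell for every flat index."""
    idx = np.indices(shape).reshape(len(shape), -1)
    comp = (np.array(shape)[:, None] - 1) - idx
    return np.ravel_multi_index(comp, shape)


def _global_counts(shape: tuple[int, ...]) -> np.ndarray:
    idx = np.indices(shape).reshape(len(shape), -1)
    return idx.sum(axis=0)


@dataclass
class FoldedMSFS:
    """Folded joint site-frequency spectrum over regions.

    Attributes
    ----------
    values : ndarray, shape ``(2*n_1+1, ..., 2*n_R+1)``
        SNP counts (observed spectra) or proportions (expected spectra).
        Non-canonical (folded-away) and masked cells are zero.
    mask : ndarray of bool, same shape
        True for canonical polymorphic cells that carry mass.
    regions : list of str
    sample_sizes : list of int
        Haploid (chromosome) sample size per region, ``2*n_r``.
    kind : "counts" or "proportions"
    meta : dict
        Free-form provenance (e.g. number of simulations behind an expected
        spectrum, number of dropped loci behind an observed one).
    """

    values: np.ndarray
    regions: list[str]
    sample_sizes: list[int]
    kind: str = "counts"
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected_shape = tuple(n + 1 for n in self.sample_sizes)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != expected_shape:
            raise ValueError(
                f"values shape {self.values.shape} != expected {expected_shape}"
            )
        if self.mask is None:
            self.mask = canonical_mask(expected_shape)
        if (self.values < 0).any():
            raise ValueError("negative SFS entries")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def total(self) -> float:
        """Total mass over unmasked cells (S for a count spectrum)."""
        return float(self.values[self.mask].sum())

    def folded(self) -> "FoldedMSFS":
        """Fold by the global minor allele.  Idempotent."""
        vals = fold_tensor(self.values)
        return FoldedMSFS(
            values=vals,
            regions=list(self.regions),
            sample_sizes=list(self.sample_sizes),
            kind=self.kind,
            meta=dict(self.meta),
        )

    def normalised(self) -> "FoldedMSFS":
        """Return proportions summing to 1 over unmasked cells."""
        s = self.total
        if s <= 0:
            raise ValueError("degenerate spectrum: no mass in polymorphic cells")
        out = np.where(self.mask, self.values / s, 0.0)
        return FoldedMSFS(
            values=out,
            regions=list(self.regions),
            sample_sizes=list(self.sample_sizes),
            kind="proportions",
            meta=dict(self.meta),
        )

    def marginal(self, region: str) -> np.ndarray:
        """Folded 1-D marginal spectrum of one region (includes cell 0)."""
        ax = tuple(i for i, r in enumerate(self.regions) if r != region)
        return self.values.sum(axis=ax)


def canonical_mask(shape: tuple[int, ...]) -> np.ndarray:
    """Boolean mask of canonical polymorphic cells after folding.

    A cell is canonical when its global count is below half the total sample,
    or equals half with a flat index no greater than its complement's.
    Monomorphic cells (global count 0 or maximal) are excluded.
    """
    n_tot = sum(s - 1 for s in shape)
    tot = _global_counts(shape)
    comp = _complement_indices(shape)
    flat = np.arange(int(np.prod(shape)))
    canon = (2 * tot < n_tot) | ((2 * tot == n_tot) & (flat <= comp))
    poly = (tot > 0) & (tot < n_tot)
    return (canon & poly).reshape(shape)


def fold_tensor(values: np.ndarray) -> np.ndarray:
    """Fold an (optionally already folded) joint spectrum tensor in place of
    the global minor allele; masked (monomorphic) cells are zeroed."""
    shape = values.shape
    flat = np.asarray(values, dtype=float).ravel().copy()
    comp = _complement_indices(shape)
    n_tot = sum(s - 1 for s in shape)
    tot = _global_counts(shape)
    idx = np.arange(flat.size)
    move = (2 * tot > n_tot) | ((2 * tot == n_tot) & (idx > comp))
    np.add.at(flat, comp[move], flat[move])
    flat[move] = 0.0
    mono = (tot == 0) | (tot == n_tot)
    flat[mono] = 0.0
    return flat.reshape(shape)


def project_counts(k: int, n: int, m: int) -> np.ndarray:
    """Hypergeometric projection of a derived-allele count.

    Returns the length ``m+1`` vector of expected fractional contributions to
    counts ``0..m`` when downsampling from ``n`` called chromosomes carrying
    ``k`` derived alleles to a subsample of ``m`` chromosomes.
    """
    if not 0 <= k <= n or m > n:
        raise ValueError("need 0 <= k <= n and m <= n")
    j = np.arange(m + 1)
    return hypergeom.pmf(j, n, k, m)


def build_folded_msfs(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    n_per_region: int,
) -> FoldedMSFS:
    """Observed folded mSFS over regions, projected down to ``n_per_region``
    diploids per region.

    Per locus and region the derived(alt)-allele count among called
    chromosomes is projected to ``2*n_per_region`` chromosomes via the
    hypergeometric expectation; the fractional contributions accumulate into
    the joint tensor, which is then folded by the global minor allele.  Loci
    with fewer than ``2*n_per_region`` called chromosomes in any region are
    dropped (count recorded in ``meta['n_dropped']``).
    """
    regions = popmap.regions
    m = 2 * n_per_region
    reg_of_pop = popmap.region_of_population()
    pop_idx = popmap.sample_indices(geno)
    region_rows = {r: [] for r in regions}
    for p, rows in pop_idx.items():
        region_rows[reg_of_pop[p]].extend(rows.tolist())
    for r in regions:
        if 2 * len(region_rows[r]) < m:
            raise ValueError(
                f"region {r!r} has {len(region_rows[r])} individuals, "
                f"fewer than projection target {n_per_region}"
            )
    shape = tuple(m + 1 for _ in regions)
    tensor = np.zeros(shape)
    calls = geno.calls
    n_dropped = 0
    for j in range(geno.n_loci):
        vecs = []
        ok = True
        for r in regions:
            rows = region_rows[r]
            g = calls[rows, j]
            called = g >= 0
            n_chr = 2 * int(called.sum())
            if n_chr < m:
                ok = False
                break
            k = int(g[called].sum())
            if n_chr == m:
                v = np.zeros(m + 1)
                v[k] = 1.0
            else:
                v = project_counts(k, n_chr, m)
            vecs.append(v)
        if not ok:
            n_dropped += 1
            continue
        hot = [np.flatnonzero(v).size == 1 for v in vecs]
        if all(hot):
            cell = tuple(int(np.flatnonzero(v)[0]) for v in vecs)
            tensor[cell] += 1.0
        else:
            tensor += _outer(vecs)
    folded = fold_tensor(tensor)
    return FoldedMSFS(
        values=folded,
        regions=regions,
        sample_sizes=[m] * len(regions),
        kind="counts",
        meta={"n_dropped": n_dropped, "n_loci": geno.n_loci},
    )


def _outer(vecs: list[np.ndarray]) -> np.ndarray:
    out = vecs[0]
    for v in vecs[1:]:
        out = np.multiply.outer(out, v)
    return out


def composite_loglik(obs: FoldedMSFS, exp: FoldedMSFS, floor: float | None = None) -> float:
    """Composite log-likelihood sum_i m_i * ln(p_i) over unmasked cells with
    observed count m_i > 0.

    Expected proportions below ``floor`` are floored to avoid -inf from
    finite-simulation zeros; the default floor is ``1 / (10 * n_sim)`` when
    the expected spectrum records its simulation count, else 1e-12.
    """
    if obs.shape != exp.shape:
        raise ValueError(f"shape mismatch: {obs.shape} vs {exp.shape}")
    if floor is None:
        n_sim = exp.meta.get("n_sim")
        floor = 1.0 / (10.0 * n_sim) if n_sim else 1e-12
    m = obs.values[obs.mask]
    p = exp.values[obs.mask]
    nz = m > 0
    return float(np.sum(m[nz] * np.log(np.maximum(p[nz], floor))))


def saturated_loglik(obs: FoldedMSFS) -> float:
    """Maximum attainable composite log-likelihood, sum m_i ln(m_i / S)."""
    m = obs.values[obs.mask]
    s = m.sum()
    if s <= 0:
        raise ValueError("empty spectrum")
    nz = m > 0
    return float(np.sum(m[nz] * np.log(m[nz] / s)))
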