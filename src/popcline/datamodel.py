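"""Shared data model: genotype matrices and hierarchical population maps.

Conventions used throughout the package:

* genotype calls are alternate-allele dosages in {0, 1, 2}; missing calls are
  the dedicated sentinel :data:`MISSING` (never 0);
* locus positions are 1-based (as in VCF); all internal array indexing is
  0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of biallelic alternate-allele dosages.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers, no duplicates.
    loci : pandas.DataFrame
        One row per locus, indexed 0..L-1, with at least a column ``id``
        (unique locus identifiers); optional columns ``chrom``, ``pos``
        (1-based) and arbitrary metadata (e.g. a ground-truth ``selected``
        flag from the simulator).
    calls : numpy.ndarray of int8, shape (n_samples, n_loci)
        Entries in {0, 1, 2, MISSING}.
    """

    samples: list[str]
    loci: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array (samples x loci)")
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        ok = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= 2))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid genotype calls {bad.tolist()}; expected 0/1/2/{MISSING}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        ids = list(self.loci["id"])
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus identifiers")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.loci["id"])

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def dosage_float(self) -> np.ndarray:
        """Calls as float with missing replaced by NaN."""
        x = self.calls.astype(float)
        x[self.calls == MISSING] = np.nan
        return x

    def subset_loci(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given locus indices or ids."""
        keep = np.asarray(keep)
        if keep.dtype.kind in "US O":
            idx = pd.Index(self.loci["id"]).get_indexer(keep)
            if (idx < 0).any():
                missing = keep[idx < 0]
                raise KeyError(f"unknown locus ids: {missing[:5].tolist()}")
        elif keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep.astype(int)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=self.loci.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx].copy(),
        )

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in keep], dtype=int)
        return GenotypeMatrix(samples=list(keep), loci=self.loci.copy(), calls=self.calls[idx])


@dataclass
class PopulationMap:
    """Hierarchy sample -> population -> region, with per-population
    coordinates (decimal degrees) and an environmental covariate
    (growing-season length, days).

    ``table`` has one row per sample with columns
    ``sample, population, region, latitude, longitude, environment``.
    """

    table: pd.DataFrame
    REQUIRED = ("sample", "population", "region", "latitude", "longitude", "environment")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"population map missing columns: {missing}")
        t = self.table
        if t["sample"].duplicated().any():
            dup = t.loc[t["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"sample {dup!r} assigned more than once")
        # each population must sit in exactly one region with one coordinate set
        per_pop = t.groupby("population")[["region", "latitude", "longitude", "environment"]].nunique()
        bad = per_pop[(per_pop > 1).any(axis=1)]
        if len(bad):
            raise ValueError(f"population(s) with inconsistent region/coordinates: {list(bad.index)}")
        if not t["latitude"].between(-90, 90).all():
            raise ValueError("latitude outside [-90, 90]")
        if not t["longitude"].between(-180, 180).all():
            raise ValueError("longitude outside [-180, 180]")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.table["region"]))

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample"], self.table["population"]))

    def region_of_population(self) -> dict[str, str]:
        t = self.table.drop_duplicates("population")
        return dict(zip(t["population"], t["region"]))

    def population_table(self) -> pd.DataFrame:
        """One row per population: region, latitude, longitude, environment."""
        cols = ["population", "region", "latitude", "longitude", "environment"]
        return self.table[cols].drop_duplicates("population").set_index("population")

    def sample_indices(self, geno: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Population -> array of row indices into ``geno.calls``.

        Every sample of ``geno`` must be assigned to exactly one population.
        """
        pop_of = self.population_of()
        unassigned = [s for s in geno.samples if s not in pop_of]
        if unassigned:
            raise ValueError(f"samples not in population map: {unassigned[:5]}")
        out: dict[str, list[int]] = {}
        for i, s in enumerate(geno.samples):
            out.setdefault(pop_of[s], []).append(i)
        return {p: np.array(v, dtype=int) for p, v in out.items()}

    def environment_per_sample(self, geno: GenotypeMatrix) -> np.ndarray:
        """Environment value of each sample (its population's value)."""
        env = self.population_table()["environment"]
        pop_of = self.population_of()
        return np.array([env[pop_of[s]] for s in geno.samples], dtype=float)
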