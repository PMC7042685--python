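"""Core in-memory containers shared across the pipeline.

The central object is :class:`GenotypeMatrix`, a diploid codominant SSR
genotype table: for each individual and locus an *unordered* pair of
positive-integer allele codes (fragment sizes or arbitrary labels), with a
population label per individual and optional WGS84 coordinates per tree.
Missing data is the pair (0, 0); half-missing genotypes are not
representable and are rejected at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = 0  # reserved allele code for a missing call


class GenotypeError(ValueError):
    """Raised when genotype data violates the container invariants."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid allele calls with population labels.

    Parameters
    ----------
    individual_ids
        Unique identifier per individual, length ``n``.
    population_labels
        Site code per individual (e.g. ``ZAT``, ``PAT``), length ``n``.
    calls
        Integer array of shape ``(n, n_loci, 2)``; allele codes are positive
        integers, ``0`` in both slots marks a missing genotype. The pair is
        unordered; callers must not rely on slot order.
    locus_names
        Length ``n_loci``.
    coordinates
        Optional ``(n, 2)`` array of (lon, lat) WGS84 decimal degrees;
        ``NaN`` rows mark trees without a location.
    """

    individual_ids: list[str]
    population_labels: list[str]
    calls: np.ndarray
    locus_names: list[str]
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise GenotypeError(
                f"calls must have shape (n, n_loci, 2), got {self.calls.shape}"
            )
        n, n_loci, _ = self.calls.shape
        if len(self.individual_ids) != n:
            raise GenotypeError("individual_ids length does not match calls")
        if len(self.population_labels) != n:
            raise GenotypeError("population_labels length does not match calls")
        if len(self.locus_names) != n_loci:
            raise GenotypeError("locus_names length does not match calls")
        if (self.calls < 0).any():
            raise GenotypeError("negative allele codes are not allowed")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise GenotypeError(
                f"half-missing genotype for individual "
                f"{self.individual_ids[i]!r} at locus {self.locus_names[l]!r}"
            )
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (n, 2):
                raise GenotypeError("coordinates must have shape (n, 2)")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p, None)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, n_loci) mask, True where the genotype is missing."""
        return (self.calls == MISSING).all(axis=2)

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.array(
            [i for i, p in enumerate(self.population_labels) if p == population],
            dtype=int,
        )
        if idx.size == 0:
            raise GenotypeError(f"unknown population {population!r}")
        return idx

    def subset(self, indices: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in idx],
            population_labels=[self.population_labels[i] for i in idx],
            calls=self.calls[idx].copy(),
            locus_names=list(self.locus_names),
            coordinates=None if self.coordinates is None else self.coordinates[idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if (
            self.individual_ids != other.individual_ids
            or self.population_labels != other.population_labels
            or self.locus_names != other.locus_names
        ):
            return False
        # genotypes are unordered pairs
        if not np.array_equal(np.sort(self.calls, 2), np.sort(other.calls, 2)):
            return False
        a, b = self.coordinates, other.coordinates
        if (a is None) != (b is None):
            return False
        if a is not None:
            both_nan = np.isnan(a) & np.isnan(b)
            if not (np.isclose(a, b, equal_nan=True) | both_nan).all():
                return False
        return True


@dataclass
class OccurrenceSet:
    """Presence/occurrence points in WGS84 lon/lat with a source tag each."""

    points: np.ndarray  # (n, 2) lon, lat
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        lon, lat = self.points[:, 0], self.points[:, 1]
        if ((lon < -180) | (lon > 180)).any():
            raise ValueError("longitude out of [-180, 180]")
        if ((lat < -90) | (lat > 90)).any():
            raise ValueError("latitude out of [-90, 90]")
        if not self.sources:
            self.sources = ["unknown"] * len(self.points)
        if len(self.sources) != len(self.points):
            raise ValueError("sources length does not match points")

    def __len__(self) -> int:
        return len(self.points)

    def deduplicate_cells(self, cell_size: float) -> "OccurrenceSet":
        """Keep one point per grid cell on the global lattice of ``cell_size``.

        The first point encountered in each cell is retained, so the result
        is deterministic for a given input order.
        """
        keys = np.floor(self.points / cell_size).astype(np.int64)
        seen: set[tuple[int, int]] = set()
        keep: list[int] = []
        for i, k in enumerate(map(tuple, keys)):
            if k not in seen:
                seen.add(k)
                keep.append(i)
        return OccurrenceSet(
            points=self.points[keep], sources=[self.sources[i] for i in keep]
        )
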