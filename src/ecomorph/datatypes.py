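"""Core containers shared across the analysis stages.

Landmark data are held as dense ``n_specimens x k_landmarks x 2`` arrays with
per-landmark roles (true landmark vs. sliding semilandmark); tabular data
(isotopes, diet, gut measurements) travel as :class:`pandas.DataFrame` with
documented column conventions; distance matrices carry their labels with them
so permutation tests can validate alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TRUE_LANDMARK = "true_landmark"
SEMILANDMARK = "semilandmark"


@dataclass
class SpecimenRecord:
    """Metadata for one specimen; ``standard_length`` is in mm when present."""

    specimen_id: str
    species: str = ""
    site: str = ""
    sex: Optional[str] = None
    standard_length: Optional[float] = None

    def __post_init__(self) -> None:
        if self.standard_length is not None and not self.standard_length > 0:
            raise ValueError(
                f"standard_length must be positive, got {self.standard_length} "
                f"for specimen {self.specimen_id!r}"
            )


@dataclass
class LandmarkSet:
    """A block of 2-D landmark configurations sharing one landmark scheme.

    ``coords`` has shape ``(n_specimens, k_landmarks, 2)``; landmark order is
    identical for every specimen.  ``roles`` flags each landmark as a true
    (homologous) landmark or a semilandmark placed along an outline curve.
    """

    records: list[SpecimenRecord]
    coords: np.ndarray
    roles: list[str] = field(default_factory=list)
    scale_units: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError(f"coords must be (n, k, 2), got {self.coords.shape}")
        n, k, _ = self.coords.shape
        if len(self.records) != n:
            raise ValueError(f"{len(self.records)} records but {n} coordinate blocks")
        if not self.roles:
            self.roles = [TRUE_LANDMARK] * k
        if len(self.roles) != k:
            raise ValueError(f"roles length {len(self.roles)} != k={k}")
        if k < 3:
            raise ValueError(f"need at least 3 landmarks, got {k}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain missing/non-finite values")
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("specimen_id values are not unique")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def semilandmark_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == SEMILANDMARK]

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(
            records=[replace(r) for r in self.records],
            coords=self.coords.copy(),
            roles=list(self.roles),
            scale_units=self.scale_units,
        )


@dataclass
class AlignedShapes:
    """Output of generalized Procrustes analysis.

    ``coords`` are Procrustes (tangent-projected) coordinates, ``centroid_sizes``
    keep the original-unit sizes removed during scaling, and ``consensus`` is the
    mean shape the sample was aligned to.
    """

    coords: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    iterations_used: int
    records: list[SpecimenRecord] = field(default_factory=list)
    residual_ss_history: list[float] = field(default_factory=list)

    def flat(self) -> np.ndarray:
        """Shape variables as an ``n x 2k`` matrix (x1, y1, x2, y2, ...)."""
        n = self.coords.shape[0]
        return self.coords.reshape(n, -1)

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]


@dataclass
class SlidingScheme:
    """Which landmarks slide and along which chord.

    ``neighbors[j]`` gives the (prev, next) landmark indices whose chord defines
    the tangent direction for semilandmark ``semilandmark_indices[j]``; endpoints
    of open curves use the semilandmark itself as one of the pair.
    """

    semilandmark_indices: list[int]
    neighbors: list[tuple[int, int]]
    iterations: int = 10

    def validate(self, k: int) -> None:
        if len(self.neighbors) != len(self.semilandmark_indices):
            raise ValueError("neighbors and semilandmark_indices differ in length")
        for j, (p, q) in zip(self.semilandmark_indices, self.neighbors):
            if not (0 <= j < k and 0 <= p < k and 0 <= q < k):
                raise ValueError(f"scheme index out of range for k={k}: {(j, p, q)}")


@dataclass
class SymmetryMap:
    """Object-symmetry layout: bilaterally paired landmarks plus midline points."""

    paired: list[tuple[int, int]]
    midline: list[int]

    def validate(self, k: int) -> None:
        seen: list[int] = []
        for left, right in self.paired:
            seen.extend([left, right])
        seen.extend(self.midline)
        if sorted(seen) != list(range(k)):
            raise ValueError(
                "symmetry map must cover every landmark exactly once "
                f"(k={k}, covered={sorted(seen)})"
            )


@dataclass
class ShapeRegressionResult:
    """Allometric regression of shape variables on log10 centroid size."""

    coefficients: np.ndarray  # 2k vector: shape change per unit log10 CS
    intercepts: np.ndarray
    residuals: np.ndarray  # n x 2k, column means zero
    percent_predicted: float


@dataclass
class Ordination:
    """Scores, orthonormal axes, and eigenvalues of a linear ordination."""

    scores: np.ndarray  # n x m
    axes: np.ndarray  # p x m, columns orthonormal
    eigenvalues: np.ndarray  # m, descending

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.axes = np.asarray(self.axes, float)
        self.eigenvalues = np.asarray(self.eigenvalues, float)


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    n_permutations: int = 0
    statistic_name: str = "F"
    pairwise: Optional[pd.DataFrame] = None
    extra: dict = field(default_factory=dict)


@dataclass
class EllipseSpec:
    """An equal-frequency (constant Mahalanobis density) ellipse."""

    center: np.ndarray
    covariance: np.ndarray
    probability: float
    area: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        from scipy.stats import chi2

        pts = np.atleast_2d(np.asarray(points, float))
        diff = pts - self.center
        inv = np.linalg.inv(self.covariance)
        md2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
        return md2 <= chi2.ppf(self.probability, df=2)

    def boundary(self, n_points: int = 256) -> np.ndarray:
        """Polygonal approximation of the ellipse boundary (n_points x 2)."""
        from scipy.stats import chi2

        q = chi2.ppf(self.probability, df=2)
        vals, vecs = np.linalg.eigh(self.covariance)
        theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
        circle = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        return self.center + circle * np.sqrt(q * vals) @ vecs.T


@dataclass
class PLSResult:
    """Two-block partial least squares output."""

    singular_values: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    score_correlations: np.ndarray
    permutation_p: np.ndarray
    n_permutations: int


@dataclass
class DistanceMatrix:
    """Labeled symmetric nonnegative matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n},{n})")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("matrix is not symmetric (tolerance 1e-12)")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        vals = df.to_numpy(dtype=float)
        vals = 0.5 * (vals + vals.T)  # absorb printing round-off
        np.fill_diagonal(vals, 0.0)
        return cls(labels=[str(c) for c in df.columns], values=vals)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries as a vector (scipy condensed order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class GenotypeData:
    """Biallelic genotypes as alternate-allele dosage (0/1/2, NaN = missing)."""

    samples: list[str]
    loci: pd.DataFrame  # columns: chrom, pos (1-based bp)
    genotypes: np.ndarray  # samples x loci, float with NaN for missing

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != "
                f"({len(self.samples)}, {len(self.loci)})"
            )
        finite = self.genotypes[np.isfinite(self.genotypes)]
        if finite.size and not np.all(np.isin(finite, [0.0, 1.0, 2.0])):
            raise ValueError("genotype values must be 0, 1, 2, or missing")
        for chrom, sub in self.loci.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)
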