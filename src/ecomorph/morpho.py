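"""Landmark superimposition and shape-variable construction.

Generalized Procrustes analysis (GPA) here is the full iterative fit: every
configuration is centered, scaled to unit centroid size, and rotated onto the
running consensus (rotation by SVD with determinant forced to +1, so
reflections are never introduced); the consensus is recomputed until it stops
moving, and the aligned coordinates are finally projected orthogonally onto
the tangent space at the consensus.  Semilandmark sliding minimizes thin-plate
-spline bending energy relative to the sample consensus, moving each
semilandmark along the chord between its curve neighbors (a closed-form linear
solve per specimen per iteration).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .datatypes import (
    AlignedShapes,
    LandmarkSet,
    ShapeRegressionResult,
    SlidingScheme,
    SymmetryMap,
)

__all__ = [
    "centroid_size",
    "gpa",
    "symmetric_component",
    "bending_energy_matrix",
    "bending_energy",
    "slide_displacements",
    "slide_semilandmarks",
    "prune_landmarks",
    "regress_shape_on_size",
    "procrustes_distance",
]


def centroid_size(config: np.ndarray) -> float:
    """Root summed squared deviations of the landmarks from their centroid."""
    config = np.asarray(config, float)
    if config.ndim != 2 or config.shape[1] != 2 or config.shape[0] < 3:
        raise ValueError(f"expected a k x 2 configuration with k >= 3, got {config.shape}")
    centered = config - config.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return size


def _center_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    size = centroid_size(config)
    return (config - config.mean(axis=0)) / size, size


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||source @ R - target||_F."""
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def gpa(data: LandmarkSet, tol: float = 1e-10, max_iter: int = 100) -> AlignedShapes:
    """Generalized Procrustes superimposition of all specimens.

    Returns Procrustes coordinates (tangent-projected), original centroid
    sizes, the consensus, and the iteration count.
    """
    if data.n_specimens < 2:
        raise ValueError("GPA needs at least 2 specimens")
    n = data.n_specimens
    scaled = np.empty_like(data.coords)
    sizes = np.empty(n)
    for i in range(n):
        scaled[i], sizes[i] = _center_scale(data.coords[i])

    consensus = scaled[0].copy()
    change = np.inf
    iterations = 0
    history: list[float] = []
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            scaled[i] = scaled[i] @ _optimal_rotation(scaled[i], consensus)
        new_consensus = scaled.mean(axis=0)
        new_consensus, _ = _center_scale(new_consensus)
        change = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        history.append(float(np.sum((scaled - consensus) ** 2)))
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3g})"
        )

    # orthogonal projection onto the tangent space at the consensus
    c = consensus.reshape(-1)
    flat = scaled.reshape(n, -1)
    flat = flat - np.outer(flat @ c - 1.0, c)
    aligned = flat.reshape(n, -1, 2)
    return AlignedShapes(
        coords=aligned,
        centroid_sizes=sizes,
        consensus=aligned.mean(axis=0),
        iterations_used=iterations,
        records=[replace(r) for r in data.records],
        residual_ss_history=history,
    )


def _mirror(coords: np.ndarray, symmetry: SymmetryMap) -> np.ndarray:
    """Reflect about the y-axis and swap paired landmark labels."""
    out = coords.copy()
    out[..., 0] *= -1.0
    perm = np.arange(coords.shape[-2])
    for left, right in symmetry.paired:
        perm[left], perm[right] = right, left
    return out[..., perm, :]


def symmetric_component(data: LandmarkSet, symmetry: SymmetryMap) -> AlignedShapes:
    """Symmetric shape component under object symmetry.

    Each specimen is doubled with its mirrored-and-relabeled copy, the doubled
    sample is superimposed by GPA, and the symmetric component is the mean of
    each original/mirror pair of aligned configurations.
    """
    symmetry.validate(data.n_landmarks)
    n = data.n_specimens
    doubled = LandmarkSet(
        records=[replace(r) for r in data.records]
        + [replace(r, specimen_id=r.specimen_id + "__mirror") for r in data.records],
        coords=np.concatenate([data.coords, _mirror(data.coords, symmetry)]),
        roles=list(data.roles),
        scale_units=data.scale_units,
    )
    fit = gpa(doubled)
    sym = 0.5 * (fit.coords[:n] + fit.coords[n:])
    return AlignedShapes(
        coords=sym,
        centroid_sizes=fit.centroid_sizes[:n],
        consensus=sym.mean(axis=0),
        iterations_used=fit.iterations_used,
        records=[replace(r) for r in data.records],
    )


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending energy matrix of a reference configuration.

    Kernel U(r) = r^2 log r^2.  The matrix is the upper-left k x k block of the
    inverse bordered TPS system; it is symmetric positive semidefinite and
    annihilates affine transforms of the reference.
    """
    ref = np.asarray(reference, float)
    k = ref.shape[0]
    d = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    if np.any(d[~np.eye(k, dtype=bool)] == 0):
        raise ValueError("duplicate landmarks make the TPS system singular")
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = np.where(d > 0, d**2 * np.log(d**2), 0.0)
    q = np.column_stack([np.ones(k), ref])
    system = np.zeros((k + 3, k + 3))
    system[:k, :k] = kernel
    system[:k, k:] = q
    system[k:, :k] = q.T
    try:
        inv = np.linalg.inv(system)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system (degenerate reference)") from exc
    be = inv[:k, :k]
    return 0.5 * (be + be.T)


def bending_energy(reference: np.ndarray, target: np.ndarray) -> float:
    """Bending energy of the TPS deformation taking reference to target."""
    be = bending_energy_matrix(reference)
    target = np.asarray(target, float)
    return float(sum(target[:, d] @ be @ target[:, d] for d in range(target.shape[1])))


def slide_displacements(
    config: np.ndarray,
    reference: np.ndarray,
    semilandmarks: list[int],
    neighbors: list[tuple[int, int]],
    be: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Chord-direction displacements minimizing one specimen's bending energy.

    Each semilandmark ``j`` moves by ``t_j`` along the unit chord through its
    (prev, next) neighbors; ``t`` solves the normal equations of the quadratic
    bending-energy objective relative to ``reference``.  Returns (t, slid
    configuration).
    """
    config = np.asarray(config, float)
    if be is None:
        be = bending_energy_matrix(reference)
    m = len(semilandmarks)
    tangents = np.empty((m, 2))
    for a, ((p, q), j) in enumerate(zip(neighbors, semilandmarks)):
        chord = config[q] - config[p]
        norm = np.linalg.norm(chord)
        if norm == 0:
            raise ValueError(f"zero-length tangent chord at semilandmark {j}")
        tangents[a] = chord / norm
    dev = config - reference
    sub = be[np.ix_(semilandmarks, semilandmarks)]
    a_mat = sub * (tangents @ tangents.T)
    b_vec = -np.array(
        [
            sum(tangents[a, d] * (be[semilandmarks[a]] @ dev[:, d]) for d in range(2))
            for a in range(m)
        ]
    )
    t, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    slid = config.copy()
    slid[semilandmarks] += t[:, None] * tangents
    return t, slid


def slide_semilandmarks(
    data: LandmarkSet,
    scheme: SlidingScheme,
    return_diagnostics: bool = False,
):
    """Slide semilandmarks along their tangent chords to minimize bending energy.

    Per iteration: superimpose (GPA), take the consensus as the TPS reference,
    then for every specimen solve the linear system giving the chord-direction
    displacements of all semilandmarks that jointly minimize the specimen's
    bending energy relative to the reference.  Within each iteration the total
    bending energy cannot increase.  Returns the slid configurations (in
    Procrustes alignment); with ``return_diagnostics`` also a per-iteration
    list of (energy before, energy after).
    """
    scheme.validate(data.n_landmarks)
    if scheme.iterations == 0:
        return (data.copy(), []) if return_diagnostics else data.copy()

    work = data.copy()
    sem = list(scheme.semilandmark_indices)
    m = len(sem)
    energy_log: list[tuple[float, float]] = []
    for _ in range(scheme.iterations):
        fit = gpa(work)
        ref = fit.consensus
        be = bending_energy_matrix(ref)
        coords = fit.coords.copy()
        pre = post = 0.0
        for i in range(coords.shape[0]):
            dev = coords[i] - ref
            pre += float(sum(dev[:, d] @ be @ dev[:, d] for d in range(2)))
            _, slid = slide_displacements(coords[i], ref, sem, scheme.neighbors, be=be)
            dev = slid - ref
            post += float(sum(dev[:, d] @ be @ dev[:, d] for d in range(2)))
            coords[i] = slid
        energy_log.append((pre, post))
        work = LandmarkSet(
            records=[replace(r) for r in work.records],
            coords=coords,
            roles=list(work.roles),
            scale_units=work.scale_units,
        )
    return (work, energy_log) if return_diagnostics else work


def prune_landmarks(data: LandmarkSet, keep: list[int]) -> LandmarkSet:
    """Subset landmarks by index, preserving order and metadata."""
    if not keep:
        raise ValueError("keep must be non-empty")
    if len(set(keep)) != len(keep):
        raise ValueError("keep contains duplicate indices")
    k = data.n_landmarks
    bad = [i for i in keep if not 0 <= i < k]
    if bad:
        raise ValueError(f"landmark indices out of range for k={k}: {bad}")
    return LandmarkSet(
        records=[replace(r) for r in data.records],
        coords=data.coords[:, keep, :].copy(),
        roles=[data.roles[i] for i in keep],
        scale_units=data.scale_units,
    )


def regress_shape_on_size(shapes: AlignedShapes) -> ShapeRegressionResult:
    """OLS of every Procrustes shape variable on log10 centroid size.

    The residuals (size-corrected shape variables) feed all downstream
    ordinations and group tests; ``percent_predicted`` is the percentage of
    total shape variance accounted for by allometry.
    """
    y = shapes.flat()
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 specimens for the allometric regression")
    x = np.log10(shapes.centroid_sizes)
    if np.ptp(x) == 0:
        raise ValueError("constant centroid size: allometry not estimable")
    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    slope = (xc @ yc) / (xc @ xc)
    fitted = np.outer(xc, slope)
    residuals = yc - fitted
    ss_total = float(np.sum(yc**2))
    ss_model = float(np.sum(fitted**2))
    return ShapeRegressionResult(
        coefficients=slope,
        intercepts=y.mean(axis=0) - slope * x.mean(),
        residuals=residuals,
        percent_predicted=100.0 * ss_model / ss_total if ss_total > 0 else 0.0,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations.

    Both are centered and scaled to unit centroid size; b is then rotated
    (no reflection) and rescaled to best fit a.  The distance is the root of
    the minimized residual sum of squares: sqrt(1 - (sum of signed singular
    values)^2).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"configurations differ in shape: {a.shape} vs {b.shape}")
    za, _ = _center_scale(a)
    zb, _ = _center_scale(b)
    u, s, vt = np.linalg.svd(zb.T @ za)
    sign = np.sign(np.linalg.det(u @ vt))
    trace = s[0] + sign * s[1]
    return float(np.sqrt(max(0.0, 1.0 - trace**2)))
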