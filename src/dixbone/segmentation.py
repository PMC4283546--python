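"""Probabilistic tissue segmentation and rigid coregistration.

An atlas-free stand-in for unified segmentation: a Gaussian mixture over
voxel intensities with a jointly estimated multiplicative polynomial bias
field, fitted by (generalized) EM.  Spatial priors are replaced by
user-supplied class-intensity seeds, which is sufficient for phantom data
whose tissue intensities are separable by construction.

Also provides rigid-body coregistration by maximizing normalized mutual
information (32x32 joint histogram, Powell search with random restarts)
and grid-to-grid resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.special import logsumexp

from .image import Image3D

__all__ = [
    "TissueProbabilityMaps",
    "RigidTransform",
    "fit_tissue_mixture",
    "coregister_rigid",
    "resample",
    "normalized_mutual_information",
    "dice",
]


@dataclass
class TissueProbabilityMaps:
    """Per-class posterior probability volumes plus the fitted mixture."""

    classes: list
    maps: dict                      # class name -> Image3D of posteriors
    means: np.ndarray
    variances: np.ndarray
    mixing: np.ndarray
    bias: Image3D
    log_likelihoods: list
    converged: bool
    degenerate_classes: list = field(default_factory=list)

    def __post_init__(self):
        total = sum(self.maps[c].data for c in self.classes)
        if not np.allclose(total, 1.0, atol=1e-6):
            raise ValueError("posteriors must sum to 1 per voxel")

    def __getitem__(self, name) -> Image3D:
        return self.maps[name]

    def hard_labels(self) -> Image3D:
        stack = np.stack([self.maps[c].data for c in self.classes])
        ref = self.maps[self.classes[0]]
        return ref.with_data(np.argmax(stack, axis=0).astype(np.int16))


def _poly_basis(shape, order):
    """Polynomial basis up to total degree `order` on [-1, 1]^3 coords,
    constant term first; shape (nvox, nterms)."""
    coords = [np.linspace(-1, 1, n) if n > 1 else np.zeros(n) for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    cols = [np.ones(x.size)]
    for total in range(1, order + 1):
        for i in range(total + 1):
            for j in range(total - i + 1):
                k = total - i - j
                cols.append((x**i * y**j * z**k).ravel())
    return np.stack(cols, axis=1)


def fit_tissue_mixture(
    image: Image3D,
    n_classes: int,
    init,
    bias_order: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    class_names=None,
    variance_floor_frac: float = 1e-6,
) -> TissueProbabilityMaps:
    """EM fit of a Gaussian mixture with a multiplicative bias field.

    Parameters
    ----------
    init : sequence of float
        Distinct starting intensities, one per class (these replace the
        spatial priors of atlas-based segmentation).
    bias_order : int
        Total degree of the polynomial bias field; 0 disables it.
    tol : float
        Relative change in observed-data log-likelihood that stops EM.

    The observed-data log-likelihood is non-decreasing across iterations
    (coordinate-ascent M-step); non-convergence within ``max_iter`` and
    variance-floored classes are reported on the result, not raised.
    """
    y = np.asarray(image.data, dtype=np.float64).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("image must be finite")
    init = np.asarray(init, dtype=np.float64)
    if n_classes < 2 or init.size != n_classes:
        raise ValueError("need n_classes >= 2 init intensities")
    if len(np.unique(init)) != n_classes:
        raise ValueError("init intensities must be distinct")
    if class_names is None:
        class_names = [f"class{k}" for k in range(n_classes)]

    n = y.size
    mu = init.copy()
    data_var = y.var()
    floor = max(variance_floor_frac * data_var, 1e-30)
    var = np.full(n_classes, max(data_var / n_classes**2, floor))
    pi = np.full(n_classes, 1.0 / n_classes)
    P = _poly_basis(image.shape, bias_order)
    beta = np.zeros(P.shape[1])
    beta[0] = 1.0
    b = P @ beta

    lls = []
    converged = False
    degenerate = set()
    gamma = np.empty((n, n_classes))
    for _ in range(max_iter):
        # E-step
        logp = np.empty((n, n_classes))
        for k in range(n_classes):
            logp[:, k] = (
                np.log(pi[k] + 1e-300)
                - 0.5 * np.log(2 * np.pi * var[k])
                - 0.5 * (y - b * mu[k]) ** 2 / var[k]
            )
        norm = logsumexp(logp, axis=1)
        lls.append(float(norm.sum()))
        gamma[:] = np.exp(logp - norm[:, None])

        if len(lls) > 1 and abs(lls[-1] - lls[-2]) <= tol * abs(lls[-2]):
            converged = True
            break

        # M-step: class parameters given the bias field
        nk = gamma.sum(axis=0)
        pi = nk / n
        for k in range(n_classes):
            denom = gamma[:, k] @ (b * b)
            mu[k] = (gamma[:, k] @ (b * y)) / denom if denom > 0 else mu[k]
            v = (gamma[:, k] @ (y - b * mu[k]) ** 2) / max(nk[k], 1e-12)
            if v < floor:
                v = floor
                degenerate.add(class_names[k])
            var[k] = v

        # M-step: bias field given class parameters (weighted least squares)
        if bias_order > 0:
            c = gamma @ (mu**2 / var)            # per-voxel curvature
            d = y * (gamma @ (mu / var))
            A = (P * c[:, None]).T @ P
            A[np.diag_indices_from(A)] += 1e-8 * max(np.trace(A), 1.0) / A.shape[0]
            beta = np.linalg.solve(A, P.T @ d)
            b = P @ beta
            scale = b.mean()
            if scale > 0:        # b*mu is invariant: normalise mean bias to 1
                b /= scale
                mu *= scale

    maps = {}
    for k, name in enumerate(class_names):
        maps[name] = image.with_data(gamma[:, k].reshape(image.shape))
    return TissueProbabilityMaps(
        classes=list(class_names),
        maps=maps,
        means=mu,
        variances=var,
        mixing=pi,
        bias=image.with_data(b.reshape(image.shape)),
        log_likelihoods=lls,
        converged=converged,
        degenerate_classes=sorted(degenerate),
    )


# ---------------------------------------------------------------------------
# rigid coregistration


@dataclass
class RigidTransform:
    """Proper rigid transform: world point p (fixed space) is sampled in the
    moving image at R(p) + t, with R = Rz @ Ry @ Rx from the three angles."""

    rotation: np.ndarray      # radians, (rx, ry, rz)
    translation: np.ndarray   # mm
    status: str = "ok"

    @classmethod
    def identity(cls, status="ok"):
        return cls(np.zeros(3), np.zeros(3), status)

    @classmethod
    def from_matrix(cls, M: np.ndarray, status="ok") -> "RigidTransform":
        """Recover (rx, ry, rz) and translation from a rigid 4x4 matrix
        with R = Rz @ Ry @ Rx."""
        R = M[:3, :3]
        ry = -np.arcsin(np.clip(R[2, 0], -1.0, 1.0))
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
        return cls(np.array([rx, ry, rz]), np.asarray(M[:3, 3], float), status)

    @property
    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        M = np.eye(4)
        M[:3, :3] = Rz @ Ry @ Rx
        M[:3, 3] = self.translation
        return M

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix), self.status)


def _histogram_entropy(counts):
    p = counts / counts.sum()
    p = p[p > 0]
    return -(p * np.log(p)).sum()


def normalized_mutual_information(a: np.ndarray, b: np.ndarray, bins=32) -> float:
    """Studholme NMI = (H(A) + H(B)) / H(A, B) from a joint histogram."""
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    hab = _histogram_entropy(joint)
    ha = _histogram_entropy(joint.sum(axis=1))
    hb = _histogram_entropy(joint.sum(axis=0))
    return (ha + hb) / max(hab, 1e-12)


def resample(
    image: Image3D,
    target: Image3D,
    transform: RigidTransform | None = None,
    interpolation: str = "linear",
) -> Image3D:
    """Resample ``image`` onto ``target``'s grid under a rigid transform.

    Values outside the source support are 0.  ``interpolation='nearest'``
    is required for label images.  Identity transform on an identical grid
    returns the data unchanged (bitwise).
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    if transform is None:
        transform = RigidTransform.identity()
    T = transform.matrix
    if image.same_grid(target) and np.allclose(T, np.eye(4), atol=1e-12):
        return target.with_data(image.data.copy())
    # target voxel -> world -> rigid -> source voxel
    M = np.linalg.inv(image.affine) @ T @ target.affine
    out = ndimage.affine_transform(
        np.asarray(image.data, float),
        M[:3, :3],
        offset=M[:3, 3],
        output_shape=target.shape,
        order=1 if interpolation == "linear" else 0,
        mode="constant",
        cval=0.0,
    )
    return target.with_data(out)


def coregister_rigid(
    moving: Image3D,
    fixed: Image3D,
    metric: str = "nmi",
    max_iter: int = 60,
    bins: int = 32,
    n_restarts: int = 3,
    seed: int = 0,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` to ``fixed``.

    Maximizes histogram-based NMI with a Powell local search started from
    the identity plus ``n_restarts - 1`` random perturbations (fixed seed).
    Identical inputs return the identity immediately; an optimizer failure
    falls back to the identity with ``status='failed'``.
    """
    if metric != "nmi":
        raise ValueError("only the 'nmi' metric is supported")
    if moving.same_grid(fixed) and np.array_equal(moving.data, fixed.data):
        return RigidTransform.identity()

    fdat = np.asarray(fixed.data, float)

    def neg_nmi(p):
        tr = RigidTransform(np.asarray(p[:3]), np.asarray(p[3:]))
        res = resample(moving, fixed, tr, "linear")
        return -normalized_mutual_information(res.data, fdat, bins=bins)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(6)]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(np.concatenate([
            rng.uniform(-0.05, 0.05, 3), rng.uniform(-5.0, 5.0, 3)]))

    best = None
    try:
        for p0 in starts:
            res = optimize.minimize(
                neg_nmi, p0, method="Powell",
                options={"maxiter": max_iter, "xtol": 1e-3, "ftol": 1e-7},
            )
            if best is None or res.fun < best.fun:
                best = res
    except Exception:
        return RigidTransform.identity(status="failed")
    if best is None or not np.all(np.isfinite(best.x)):
        return RigidTransform.identity(status="failed")
    return RigidTransform(best.x[:3].copy(), best.x[3:].copy())


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 1.0
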