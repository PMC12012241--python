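"""Lesion centroid and longest axis from covariance/inertia eigenanalysis.

For a lesion point cloud with centred coordinates :math:`r_k` the two
operative matrices are the (population) covariance

.. math:: C = \\frac{1}{N}\\sum_k r_k r_k^T

and the unit-mass inertia tensor

.. math:: I = \\sum_k \\left[(r_k \\cdot r_k)\\,\\mathrm{Id} - r_k r_k^T\\right].

They share eigenvectors: with scatter :math:`S = \\sum_k r_k r_k^T`,
:math:`I = \\mathrm{tr}(S)\\,\\mathrm{Id} - S`, so the eigenvector of the
*smallest* inertia eigenvalue equals the eigenvector of the *largest*
covariance eigenvalue — the lesion's longest axis, along which a drainage
catheter covers the most hematoma.  The L1 path runs along this axis into
the centroid, entering at a fixed stand-off distance (clinically 10-15 cm)
or at the skull surface, whichever is closer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import LesionPointCloud, SurfaceMesh

__all__ = [
    "PrincipalAxes",
    "Trajectory",
    "compute_centroid",
    "covariance_matrix",
    "inertia_matrix",
    "longest_axis",
    "build_l1",
    "normalize_axis_sign",
]

ISOTROPY_RATIO = 1.05  # flag near-spherical clouds: lambda1/lambda2 below this
DEFAULT_ENTRY_DISTANCE_MM = 125.0  # midpoint of the 10-15 cm clinical stand-off


@dataclass(frozen=True)
class Trajectory:
    """Oriented puncture line from skin entry to intracranial target."""

    entry: np.ndarray
    target: np.ndarray
    label: str = "manual"
    clipped_to_skull: bool = False

    def __post_init__(self):
        entry = np.asarray(self.entry, dtype=float)
        target = np.asarray(self.target, dtype=float)
        if np.linalg.norm(target - entry) <= 0:
            raise ValueError("trajectory must have distinct entry and target points")
        object.__setattr__(self, "entry", entry)
        object.__setattr__(self, "target", target)

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(self.target - self.entry))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from entry toward target."""
        return (self.target - self.entry) / self.length_mm


@dataclass(frozen=True)
class PrincipalAxes:
    """Eigen-structure of a lesion point cloud.

    ``covariance_eigenvalues`` sorted descending, ``inertia_eigenvalues``
    ascending; paired columns of the eigenvector matrices correspond.
    ``longest_axis`` is sign-normalised so its z-component is >= 0
    (ties: y >= 0, then x >= 0).
    """

    centroid: np.ndarray
    covariance_eigenvalues: np.ndarray
    covariance_eigenvectors: np.ndarray  # columns, paired with eigenvalues
    inertia_eigenvalues: np.ndarray
    inertia_eigenvectors: np.ndarray
    longest_axis: np.ndarray
    anisotropy: float
    isotropy_flag: bool

    def to_dict(self) -> dict:
        return {
            "centroid_mm": [float(v) for v in self.centroid],
            "longest_axis": [float(v) for v in self.longest_axis],
            "cov_eigenvalues": [float(v) for v in self.covariance_eigenvalues],
            "inertia_eigenvalues": [float(v) for v in self.inertia_eigenvalues],
            "anisotropy": float(self.anisotropy),
            "isotropy_flag": bool(self.isotropy_flag),
        }


def compute_centroid(cloud: LesionPointCloud) -> np.ndarray:
    """Unweighted arithmetic mean of the lesion points (mm)."""
    return cloud.points.mean(axis=0)


def _centered(cloud: LesionPointCloud) -> np.ndarray:
    if len(cloud) < 2:
        raise ValueError("need at least 2 points")
    return cloud.points - cloud.points.mean(axis=0)


def covariance_matrix(cloud: LesionPointCloud) -> np.ndarray:
    """Population (divide-by-N) covariance of the centred coordinates."""
    r = _centered(cloud)
    return r.T @ r / len(r)


def inertia_matrix(cloud: LesionPointCloud) -> np.ndarray:
    """Unit-point-mass inertia tensor about the centroid:
    ``I = sum_k [(r_k . r_k) Id - r_k r_k^T]``."""
    r = _centered(cloud)
    scatter = r.T @ r
    return np.trace(scatter) * np.eye(3) - scatter


def normalize_axis_sign(v: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Deterministic sign for an axis: z >= 0, tie-break y >= 0, then x >= 0."""
    v = np.asarray(v, dtype=float)
    for comp in (2, 1, 0):
        if v[comp] > tol:
            return v
        if v[comp] < -tol:
            return -v
    return v


def longest_axis(cloud: LesionPointCloud) -> PrincipalAxes:
    """Principal axes of the cloud; the longest axis is the eigenvector of
    the smallest inertia eigenvalue (equivalently the largest covariance
    eigenvalue).  Near-isotropic clouds (``lambda1/lambda2 < 1.05``) carry
    an isotropy warning flag — the axis is then poorly determined."""
    if len(cloud) < 4:
        raise ValueError("need at least 4 points for a stable axis estimate")
    centroid = compute_centroid(cloud)
    cov = covariance_matrix(cloud)
    cov_vals, cov_vecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(cov_vals)[::-1]
    cov_vals = cov_vals[order]
    cov_vecs = cov_vecs[:, order]

    inertia = inertia_matrix(cloud)
    in_vals, in_vecs = np.linalg.eigh(inertia)  # ascending: smallest first

    axis = normalize_axis_sign(in_vecs[:, 0])
    anisotropy = float(cov_vals[0] / cov_vals[1]) if cov_vals[1] > 0 else np.inf
    return PrincipalAxes(
        centroid=centroid,
        covariance_eigenvalues=cov_vals,
        covariance_eigenvectors=cov_vecs,
        inertia_eigenvalues=in_vals,
        inertia_eigenvectors=in_vecs,
        longest_axis=axis,
        anisotropy=anisotropy,
        isotropy_flag=anisotropy < ISOTROPY_RATIO,
    )


def build_l1(
    axes: PrincipalAxes,
    entry_distance_mm: float = DEFAULT_ENTRY_DISTANCE_MM,
    skull: SurfaceMesh | None = None,
) -> Trajectory:
    """L1 path: target at the centroid, entry at ``entry_distance_mm`` along
    the longest axis toward the superior hemisphere.

    With a skull mesh, the entry is clipped to the outer-surface exit point
    when the skull is closer than the requested stand-off (recorded in
    ``clipped_to_skull``).
    """
    if entry_distance_mm <= 0:
        raise ValueError("entry distance must be positive")
    direction = normalize_axis_sign(axes.longest_axis)
    entry = axes.centroid + entry_distance_mm * direction
    clipped = False
    if skull is not None:
        from .trajectory import ray_surface_exit, outer_skull_surface

        exit_point = ray_surface_exit(axes.centroid, direction, outer_skull_surface(skull))
        if exit_point is not None:
            exit_dist = float(np.linalg.norm(exit_point - axes.centroid))
            if exit_dist < entry_distance_mm:
                entry = exit_point
                clipped = True
    return Trajectory(entry=entry, target=axes.centroid, label="L1", clipped_to_skull=clipped)
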