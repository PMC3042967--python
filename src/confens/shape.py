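"""Gaussian-volume molecular shape model and Shape-Tanimoto similarity.

Each heavy atom is represented by an isotropic Gaussian density
``rho_i(r) = p * exp(-alpha_i * |r - c_i|^2)`` whose integral equals the
atom's hard-sphere volume (4/3) * pi * r_i^3, fixing

    alpha_i = pi * (3 p / (4 pi r_i^3))^(2/3)

with amplitude ``p = 2.7`` (the standard soft-Gaussian choice).  Molecular
densities are first-order sums of atom Gaussians; overlap volumes are the
analytic pairwise Gaussian product integrals, and the Shape-Tanimoto score

    ST = V_AB / (V_AA + V_BB - V_AB)

ranges from 0 (no similarity) to 1 (identical molecules).  The
shape-optimised ST maximises V_AB over proper rigid motions of the second
shape from a deterministic set of principal-axes starting points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .molgraph import Conformer, MoleculeGraph, PerceivedGraph

__all__ = [
    "VDW_RADII",
    "DEFAULT_RADIUS",
    "GAUSSIAN_AMPLITUDE",
    "GaussianShape",
    "OverlayResult",
    "build_shape",
    "overlap_volume",
    "shape_tanimoto",
]

#: Bondi-style van der Waals radii (Å), fixed for reproducibility.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}
DEFAULT_RADIUS = 1.70
GAUSSIAN_AMPLITUDE = 2.7


@dataclass
class GaussianShape:
    """Heavy-atom Gaussian density: centers (Å), radii (Å), derived exponents (Å^-2)."""

    centers: np.ndarray
    radii: np.ndarray
    amplitude: float = GAUSSIAN_AMPLITUDE

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float)
        if self.centers.shape[0] == 0:
            raise ValueError("shape must contain at least one heavy atom")
        if self.centers.shape[0] != self.radii.shape[0]:
            raise ValueError("centers and radii must have equal length")
        self.exponents = np.pi * (3 * self.amplitude / (4 * np.pi * self.radii**3)) ** (2 / 3)

    @property
    def n_atoms(self) -> int:
        return int(self.centers.shape[0])

    def volume(self) -> float:
        """Integral of the summed density; equals sum of hard-sphere atom volumes."""
        return float(np.sum(self.amplitude * (np.pi / self.exponents) ** 1.5))

    def self_overlap(self) -> float:
        return overlap_volume(self, self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "GaussianShape":
        return GaussianShape(
            centers=self.centers @ np.asarray(rotation).T + translation,
            radii=self.radii,
            amplitude=self.amplitude,
        )


@dataclass
class OverlayResult:
    """Shape-Tanimoto score, overlap volume (Å^3) and the rigid transform used."""

    st: float
    v_ab: float
    v_aa: float
    v_bb: float
    rotation: np.ndarray
    translation: np.ndarray
    converged: bool = True


def build_shape(conf: Conformer, p: PerceivedGraph | MoleculeGraph) -> GaussianShape:
    """Gaussian shape of a conformer's heavy atoms; unknown elements get the default radius."""
    mol = p.base if isinstance(p, PerceivedGraph) else p
    heavy = mol.heavy_indices
    if not heavy:
        raise ValueError(f"molecule {mol.name!r} has no heavy atoms")
    radii = []
    for i in heavy:
        elem = mol.atoms[i][0]
        if elem not in VDW_RADII:
            warnings.warn(
                f"no vdW radius for element {elem!r}; using default {DEFAULT_RADIUS} Å",
                stacklevel=2,
            )
        radii.append(VDW_RADII.get(elem, DEFAULT_RADIUS))
    return GaussianShape(centers=conf.coords[list(heavy)], radii=np.array(radii))


def overlap_volume(a: GaussianShape, b: GaussianShape) -> float:
    """First-order analytic overlap volume: pairwise Gaussian product integrals.

    For Gaussians i in A and j in B the product integral is
    ``p^2 (pi/(a_i+a_j))^{3/2} exp(-a_i a_j d_ij^2 / (a_i+a_j))``; the
    overlap is the sum over all pairs.  ``overlap_volume(a, a)`` is the
    self-overlap V_AA, including the i = j terms.
    """
    d2 = np.sum((a.centers[:, None, :] - b.centers[None, :, :]) ** 2, axis=-1)
    ai = a.exponents[:, None]
    aj = b.exponents[None, :]
    s = ai + aj
    terms = (
        a.amplitude * b.amplitude * (np.pi / s) ** 1.5 * np.exp(-ai * aj * d2 / s)
    )
    return float(terms.sum())


def _principal_axes(shape: GaussianShape) -> np.ndarray:
    """Proper-rotation matrix whose rows are the shape's principal axes."""
    centered = shape.centers - shape.centers.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1].T  # descending variance
    if np.linalg.det(axes) < 0:
        axes[2] *= -1
    return axes


def _overlap_at(params: np.ndarray, a: GaussianShape, b: GaussianShape) -> float:
    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    moved = b.transformed(rot, params[3:])
    return overlap_volume(a, moved)


def shape_tanimoto(
    a: GaussianShape,
    b: GaussianShape,
    optimize: bool = True,
    maxiter: int = 500,
    tol: float = 1e-6,
) -> OverlayResult:
    """Shape-Tanimoto similarity; optionally maximised over rigid motions of ``b``.

    The overlay search is deterministic multi-start: centroids are aligned,
    the principal axes of ``b`` are rotated onto those of ``a`` directly and
    through the three 180° axis flips (plus the identity orientation), and
    each start is refined by Nelder-Mead on (rotation vector, translation).
    The best overlap found is reported even if an optimiser start failed to
    converge (flagged via ``converged``).
    """
    v_aa = overlap_volume(a, a)
    v_bb = overlap_volume(b, b)

    if not optimize:
        v_ab = overlap_volume(a, b)
        return OverlayResult(
            st=v_ab / (v_aa + v_bb - v_ab),
            v_ab=v_ab,
            v_aa=v_aa,
            v_bb=v_bb,
            rotation=np.eye(3),
            translation=np.zeros(3),
        )

    ca = a.centers.mean(axis=0)
    cb = b.centers.mean(axis=0)
    axes_a = _principal_axes(a)
    axes_b = _principal_axes(b)

    starts: list[np.ndarray] = [np.eye(3), axes_a.T @ axes_b]
    for axis in range(3):
        flip = np.diag([1.0 if k == axis else -1.0 for k in range(3)])
        starts.append(axes_a.T @ flip @ axes_b)

    best_v = -np.inf
    best_params = None
    converged = True
    for r0 in starts:
        rv0 = Rotation.from_matrix(r0).as_rotvec()
        t0 = ca - r0 @ cb
        x0 = np.concatenate([rv0, t0])
        v0 = _overlap_at(x0, a, b)
        if v0 > best_v:
            best_v, best_params = v0, x0
        res = minimize(
            lambda x: -_overlap_at(x, a, b),
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": tol, "fatol": tol},
        )
        converged = converged and bool(res.success)
        if -res.fun > best_v:
            best_v, best_params = -res.fun, res.x
    assert best_params is not None
    rot = Rotation.from_rotvec(best_params[:3]).as_matrix()
    v_ab = best_v
    return OverlayResult(
        st=v_ab / (v_aa + v_bb - v_ab),
        v_ab=float(v_ab),
        v_aa=v_aa,
        v_bb=v_bb,
        rotation=rot,
        translation=best_params[3:].copy(),
        converged=converged,
    )
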