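"""Elastic half-space substrate and its surface Green's function.

The substrate is modeled as a homogeneous, isotropic, linear elastic
half-space (a thick, flat gel).  A tangential point force applied at the
surface displaces the surface according to the Boussinesq solution; only
the in-plane 2x2 block of the Green's tensor is used, since standard 2-D
traction force microscopy measures in-plane displacements only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ElasticSubstrate:
    """Material constants of the linear elastic half-space.

    Parameters
    ----------
    youngs_modulus : float
        Young's modulus E in Pa.  Must be positive.
    poisson_ratio : float
        Poisson's ratio nu, dimensionless, in [0, 0.5].
    """

    youngs_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError(f"youngs_modulus must be > 0, got {self.youngs_modulus}")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError(f"poisson_ratio must be in [0, 0.5], got {self.poisson_ratio}")


class SingularSeparationError(ValueError):
    """Raised when the Green's tensor is evaluated at zero separation."""


def greens_tensor(x, substrate: ElasticSubstrate) -> np.ndarray:
    """In-plane Boussinesq surface Green's tensor for a tangential point force.

    G_ij(x) = (1 + nu) / (pi E) * [ (1 - nu) delta_ij / r + nu x_i x_j / r^3 ]

    with r = |x|.  The result has units of length / stress and maps a point
    force density to a surface displacement.

    Parameters
    ----------
    x : array_like, shape (2,)
        Separation vector between observation point and force location.
    substrate : ElasticSubstrate

    Returns
    -------
    ndarray, shape (2, 2)
        Symmetric tensor G.

    Raises
    ------
    SingularSeparationError
        If |x| == 0.  The self-term of a discretized operator must come from
        integrating the Green's function against a shape function, never from
        a pointwise evaluation.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (2,):
        raise ValueError(f"x must be a 2-vector, got shape {x.shape}")
    r = float(np.hypot(x[0], x[1]))
    if r == 0.0:
        raise SingularSeparationError("Green's tensor is singular at zero separation")
    E = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    pref = (1.0 + nu) / (np.pi * E)
    g = pref * (1.0 - nu) / r * np.eye(2)
    g += pref * nu * np.outer(x, x) / r**3
    return g


def greens_tensor_batch(dx: np.ndarray, dy: np.ndarray, substrate: ElasticSubstrate):
    """Vectorized Green's tensor components over arrays of separations.

    Returns (gxx, gxy, gyy) broadcast to the shape of ``dx``.  Entries at
    exactly zero separation come out non-finite; callers are responsible for
    regularizing those (e.g. via shape-function integration).
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    E = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    pref = (1.0 + nu) / (np.pi * E)
    r2 = dx * dx + dy * dy
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(r2)
        inv_r = 1.0 / r
        inv_r3 = inv_r / r2
        gxx = pref * ((1.0 - nu) * inv_r + nu * dx * dx * inv_r3)
        gyy = pref * ((1.0 - nu) * inv_r + nu * dy * dy * inv_r3)
        gxy = pref * nu * dx * dy * inv_r3
    return gxx, gxy, gyy
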