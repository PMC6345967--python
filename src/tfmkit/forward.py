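"""Discrete forward model u = M f for the elastic half-space.

The traction field is discretized on a regular grid and interpolated with
pyramidal (bilinear "hat") shape functions of half-width equal to the mesh
constant.  The displacement produced at a point x by unit traction at node
x_j is then the convolution of the Boussinesq Green's tensor with the shape
function,

    T(x - x_j) = integral G(x - x') h(x' - x_j) d^2 x'.

Because T depends only on the separation, the operator on a regular grid is
a discrete convolution.  Three assembly routes are provided:

``assemble_regular``
    Samples the Green's tensor on a grid oversampled relative to the mesh,
    regularizes the 1/r singularity by replacing near-origin samples with
    exact cell averages, convolves with the sampled shape function by FFT
    (as an exact linear convolution, so there is no periodic wrap-around),
    and reads the nodal kernel off the result.

``assemble_irregular``
    Evaluates the same FFT-assembled kernel at off-lattice sample points by
    multiplying its spectrum with the Fourier shift-theorem phase factor
    exp(i k . delta) before the inverse transform.

``assemble_direct``
    Slow reference: per-entry 2-D Gauss quadrature of the convolution
    integral, with a polar triangle-fan scheme for (near-)singular entries.
    The radial part of the polar integral uses the fact that G(r e) * r
    depends only on the direction e, which removes the singularity exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.signal import fftconvolve

from .grids import TractionGrid, UnitMismatchError, _unit_scale
from .substrate import ElasticSubstrate, greens_tensor_batch

__all__ = [
    "ForwardOperator",
    "assemble_regular",
    "assemble_irregular",
    "assemble_direct",
    "predict",
]


@dataclass
class ForwardOperator:
    """Dense 2m x 2n linear map from nodal traction (Pa) to displacement.

    Row layout 2i + a (a = 0: x, 1: y component at sample i); column layout
    2j + b analogously for node j.  Matrix entries have units
    ``length_unit`` per Pa.
    """

    matrix: np.ndarray
    source_grid: TractionGrid
    target_positions: np.ndarray
    assembly_method: str
    substrate: ElasticSubstrate
    length_unit: str = "um"

    def __post_init__(self) -> None:
        m = self.target_positions.shape[0]
        n = self.source_grid.n_nodes
        if self.matrix.shape != (2 * m, 2 * n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with m={m}, n={n}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("operator matrix contains non-finite entries")
        if self.length_unit != self.source_grid.length_unit:
            raise UnitMismatchError("operator and grid length units differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def predict(self, f: np.ndarray) -> np.ndarray:
        """Noise-free displacement M f for a traction vector f (length 2n)."""
        f = np.asarray(f, dtype=float).ravel()
        if f.size != self.matrix.shape[1]:
            raise ValueError(
                f"traction vector length {f.size} != {self.matrix.shape[1]}"
            )
        return self.matrix @ f

    def in_units(self, unit: str, pixel_size: float | None = None) -> "ForwardOperator":
        """Convert the operator's length unit (matrix entries scale with it)."""
        s = _unit_scale(self.length_unit, unit, pixel_size)
        if s == 1.0:
            return self
        return ForwardOperator(
            matrix=self.matrix * s,
            source_grid=self.source_grid.in_units(unit, pixel_size),
            target_positions=self.target_positions * s,
            assembly_method=self.assembly_method,
            substrate=self.substrate,
            length_unit=unit,
        )

    def save(self, path: str) -> None:
        """Save matrix (.npz) plus a JSON metadata sidecar (.json)."""
        np.savez_compressed(path, matrix=self.matrix,
                            target_positions=self.target_positions)
        meta = {
            "assembly_method": self.assembly_method,
            "length_unit": self.length_unit,
            "youngs_modulus": self.substrate.youngs_modulus,
            "poisson_ratio": self.substrate.poisson_ratio,
            "grid_shape": list(self.source_grid.shape),
            "mesh_constant": self.source_grid.mesh_constant,
            "grid_origin": list(self.source_grid.origin),
        }
        with open(_sidecar(path), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "ForwardOperator":
        with open(_sidecar(path)) as fh:
            meta = json.load(fh)
        npz = np.load(path if path.endswith(".npz") else path + ".npz")
        grid = TractionGrid(
            shape=tuple(meta["grid_shape"]),
            mesh_constant=meta["mesh_constant"],
            origin=tuple(meta["grid_origin"]),
            length_unit=meta["length_unit"],
        )
        return cls(
            matrix=npz["matrix"],
            source_grid=grid,
            target_positions=npz["target_positions"],
            assembly_method=meta["assembly_method"],
            substrate=ElasticSubstrate(meta["youngs_modulus"], meta["poisson_ratio"]),
            length_unit=meta["length_unit"],
        )


def _sidecar(path: str) -> str:
    base = path[:-4] if path.endswith(".npz") else path
    return base + ".json"


def predict(operator: ForwardOperator, f: np.ndarray) -> np.ndarray:
    """Evaluate the forward map, u = M f."""
    return operator.predict(f)


# ---------------------------------------------------------------------------
# Green's-function cell averages (singularity regularization)
# ---------------------------------------------------------------------------

def _polar_cell_average(x0, x1, y0, y1, substrate, n_theta=32):
    """Exact average of G over the rectangle [x0,x1]x[y0,y1].

    Uses a signed triangle-fan around the origin: for each edge (A, B) of the
    counterclockwise rectangle, the signed polar integral of G over the
    triangle (0, A, B) is  int_thetaA^thetaB  Gfac(theta) R(theta) dtheta,
    where Gfac(theta) = G(r e(theta)) * r depends only on theta and R is the
    distance from the origin to the edge line.  The sum over edges equals the
    rectangle integral whether or not the origin lies inside.
    """
    E = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    pref = (1.0 + nu) / (np.pi * E)
    verts = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)
    t, w = leggauss(n_theta)
    t = 0.5 * (t + 1.0)  # [0, 1]
    w = 0.5 * w
    total = np.zeros(3)  # xx, xy, yy
    for k in range(4):
        a = verts[k]
        b = verts[(k + 1) % 4]
        cross = a[0] * b[1] - a[1] * b[0]
        dot = a @ b
        dtheta = np.arctan2(cross, dot)  # signed angular extent
        if dtheta == 0.0:
            continue
        theta_a = np.arctan2(a[1], a[0])
        theta = theta_a + t * dtheta
        e = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        # distance from origin to the line through a, b along e
        n_vec = np.array([b[1] - a[1], -(b[0] - a[0])])
        c = n_vec @ a
        denom = e @ n_vec
        R = c / denom
        fac = pref * (
            (1.0 - nu) * np.array([1.0, 0.0, 1.0])[None, :]
            + nu * np.stack([e[:, 0] ** 2, e[:, 0] * e[:, 1], e[:, 1] ** 2], axis=1)
        )
        total += dtheta * np.einsum("q,qc,q->c", w, fac, R)
    area = (x1 - x0) * (y1 - y0)
    return total / area


def _fine_kernel(grid: TractionGrid, substrate: ElasticSubstrate, oversample: int):
    """Sampled nodal kernel T = G * h on a fine grid of spacing mesh/oversample.

    Returns (txx, txy, tyy) arrays of shape (2*Ky+1, 2*Kx+1), indexed
    [Ky + ky, Kx + kx] for the offset (kx, ky) * d, together with (Kx, Ky, d).
    The offset range covers +/- (n_axis + 1) mesh constants so that both the
    regular lattice kernel and the shifted evaluation stay inside it.
    """
    a = grid.mesh_constant
    d = a / oversample
    nx, ny = grid.shape
    Kx = oversample * (nx + 1)
    Ky = oversample * (ny + 1)
    kx = np.arange(-Kx, Kx + 1) * d
    ky = np.arange(-Ky, Ky + 1) * d
    dx, dy = np.meshgrid(kx, ky)
    gxx, gxy, gyy = greens_tensor_batch(dx, dy, substrate)
    # regularize near-origin samples with exact cell averages
    half = d / 2.0
    nr = oversample  # every sample within one mesh constant of the origin
    for iy in range(-nr, nr + 1):
        for ix in range(-nr, nr + 1):
            cx, cy = ix * d, iy * d
            axx, axy, ayy = _polar_cell_average(cx - half, cx + half,
                                                cy - half, cy + half, substrate)
            gxx[Ky + iy, Kx + ix] = axx
            gxy[Ky + iy, Kx + ix] = axy
            gyy[Ky + iy, Kx + ix] = ayy
    # sampled pyramidal shape function, support +/- mesh constant
    j = np.arange(-oversample, oversample + 1)
    hat = 1.0 - np.abs(j) / oversample
    h2 = np.outer(hat, hat)
    cell = d * d
    txx = fftconvolve(gxx, h2, mode="same") * cell
    txy = fftconvolve(gxy, h2, mode="same") * cell
    tyy = fftconvolve(gyy, h2, mode="same") * cell
    return (txx, txy, tyy), (Kx, Ky, d)


def _fill_blocks(M, txx, txy, tyy):
    M[0::2, 0::2] = txx
    M[0::2, 1::2] = txy
    M[1::2, 0::2] = txy
    M[1::2, 1::2] = tyy


def assemble_regular(grid: TractionGrid, substrate: ElasticSubstrate,
                     oversample: int = 8) -> ForwardOperator:
    """Assemble the operator for displacements sampled at the grid nodes.

    The kernel is computed once on the fine grid and gathered at lattice
    offsets; assembly cost is dominated by a single FFT convolution.
    """
    nx, ny = grid.shape
    if grid.n_nodes < 4:
        raise ValueError("degenerate grid")
    (txx, txy, tyy), (Kx, Ky, d) = _fine_kernel(grid, substrate, oversample)
    # lattice-offset kernel tables, index [ny-1 + dy, nx-1 + dx]
    sub_y = Ky + oversample * np.arange(-(ny - 1), ny)
    sub_x = Kx + oversample * np.arange(-(nx - 1), nx)
    lat_xx = txx[np.ix_(sub_y, sub_x)]
    lat_xy = txy[np.ix_(sub_y, sub_x)]
    lat_yy = tyy[np.ix_(sub_y, sub_x)]
    n = grid.n_nodes
    ix = np.tile(np.arange(nx), ny)
    iy = np.repeat(np.arange(ny), nx)
    dxi = (nx - 1) + (ix[:, None] - ix[None, :])
    dyi = (ny - 1) + (iy[:, None] - iy[None, :])
    M = np.empty((2 * n, 2 * n))
    _fill_blocks(M, lat_xx[dyi, dxi], lat_xy[dyi, dxi], lat_yy[dyi, dxi])
    return ForwardOperator(
        matrix=M,
        source_grid=grid,
        target_positions=grid.node_positions,
        assembly_method="fft_regular",
        substrate=substrate,
        length_unit=grid.length_unit,
    )


def assemble_irregular(sample_positions, grid: TractionGrid,
                       substrate: ElasticSubstrate, oversample: int = 8,
                       shift_oversample: int = 4,
                       chunk: int = 32) -> ForwardOperator:
    """Assemble the operator for arbitrary sample positions (shift theorem).

    The fine kernel's spectrum is multiplied per sample by the phase factor
    exp(i k . delta) of that sample's sub-lattice offset delta, the inverse
    FFT yields the kernel on the shifted lattice, and the rows are gathered
    from it.  Samples coincident with grid nodes reproduce the regular
    assembly to machine precision.
    """
    sample_positions = np.asarray(sample_positions, dtype=float)
    if sample_positions.ndim != 2 or sample_positions.shape[1] != 2:
        raise ValueError("sample_positions must have shape (m, 2)")
    nx, ny = grid.shape
    a = grid.mesh_constant
    ox, oy = grid.origin
    ex, ey = grid.extent
    pad = a * (1.0 + 1e-9)
    if (np.any(sample_positions[:, 0] < ox - pad)
            or np.any(sample_positions[:, 0] > ox + ex + pad)
            or np.any(sample_positions[:, 1] < oy - pad)
            or np.any(sample_positions[:, 1] > oy + ey + pad)):
        raise ValueError("sample positions outside the padded grid domain")
    if oversample % shift_oversample != 0:
        raise ValueError("shift_oversample must divide oversample")
    s = shift_oversample
    b = a / s
    (txx, txy, tyy), (Kx, Ky, d) = _fine_kernel(grid, substrate, oversample)
    step = oversample // s
    Qx = 2 * s * (nx + 1)
    Qy = 2 * s * (ny + 1)
    # periodic kernel arrays: position (k mod Q) holds offset k * b
    kxs = np.arange(Qx)
    kys = np.arange(Qy)
    kx_signed = np.where(kxs < Qx // 2, kxs, kxs - Qx)
    ky_signed = np.where(kys < Qy // 2, kys, kys - Qy)
    gx = Kx + step * kx_signed
    gy = Ky + step * ky_signed
    per_xx = txx[np.ix_(gy, gx)]
    per_xy = txy[np.ix_(gy, gx)]
    per_yy = tyy[np.ix_(gy, gx)]
    spec_a = np.fft.fft2(per_xx + 1j * per_xy)
    spec_b = np.fft.fft2(per_yy).astype(complex)
    wx = 2.0 * np.pi * np.fft.fftfreq(Qx, d=b)
    wy = 2.0 * np.pi * np.fft.fftfreq(Qy, d=b)

    q = (sample_positions - np.array([ox, oy])) / a
    base = np.floor(q + 1e-12)
    delta = (q - base) * a  # in [0, a)
    m = sample_positions.shape[0]
    n = grid.n_nodes
    jx = np.arange(nx)
    jy = np.arange(ny)
    M = np.empty((2 * m, 2 * n))
    for start in range(0, m, chunk):
        idx = slice(start, min(start + chunk, m))
        dl = delta[idx]
        # per-axis phase factors; the Nyquist bin uses the real (cosine)
        # factor so that shifted kernels stay exactly real
        px = np.exp(1j * np.outer(dl[:, 0], wx))
        py = np.exp(1j * np.outer(dl[:, 1], wy))
        px[:, Qx // 2] = np.cos(dl[:, 0] * wx[Qx // 2])
        py[:, Qy // 2] = np.cos(dl[:, 1] * wy[Qy // 2])
        phase = py[:, :, None] * px[:, None, :]
        shifted_a = np.fft.ifft2(spec_a[None] * phase, axes=(-2, -1))
        shifted_b = np.fft.ifft2(spec_b[None] * phase, axes=(-2, -1))
        sxx = shifted_a.real
        sxy = shifted_a.imag
        syy = shifted_b.real
        for local, gi in enumerate(range(idx.start, idx.stop)):
            cx = (s * (int(base[gi, 0]) - jx)) % Qx
            cy = (s * (int(base[gi, 1]) - jy)) % Qy
            rxx = sxx[local][np.ix_(cy, cx)].ravel()
            rxy = sxy[local][np.ix_(cy, cx)].ravel()
            ryy = syy[local][np.ix_(cy, cx)].ravel()
            M[2 * gi, 0::2] = rxx
            M[2 * gi, 1::2] = rxy
            M[2 * gi + 1, 0::2] = rxy
            M[2 * gi + 1, 1::2] = ryy
    return ForwardOperator(
        matrix=M,
        source_grid=grid,
        target_positions=sample_positions,
        assembly_method="shift_theorem_irregular",
        substrate=substrate,
        length_unit=grid.length_unit,
    )


# ---------------------------------------------------------------------------
# Direct quadrature (reference oracle)
# ---------------------------------------------------------------------------

def _hat2(x, y, a):
    return np.clip(1.0 - np.abs(x) / a, 0.0, None) * np.clip(1.0 - np.abs(y) / a, 0.0, None)


def _fan_entry(p, node, a, substrate, n_theta, n_r):
    """Polar triangle-fan integral of G(x - p) h(x - node) over the support.

    Works for p inside or near the support square [node +/- a]^2.  Per edge
    of the square the signed triangle (p, A, B) is integrated in polar
    coordinates around p; the radial integrand Gfac(theta) h(p + r e(theta))
    is bounded because G(r e) * r depends only on theta.
    """
    E = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    pref = (1.0 + nu) / (np.pi * E)
    verts = np.array(
        [
            [node[0] - a, node[1] - a],
            [node[0] + a, node[1] - a],
            [node[0] + a, node[1] + a],
            [node[0] - a, node[1] + a],
        ]
    ) - p
    tt, wt = leggauss(n_theta)
    tt = 0.5 * (tt + 1.0)
    wt = 0.5 * wt
    # radial rule: a few equal segments catch the kinks of the piecewise
    # linear shape function along the ray
    n_seg = 6
    tr, wr = leggauss(n_r)
    tr = 0.5 * (tr + 1.0)
    wr = 0.5 * wr
    seg0 = np.arange(n_seg) / n_seg
    rfrac = (seg0[:, None] + tr[None, :] / n_seg).ravel()
    rw = np.tile(wr / n_seg, n_seg)
    total = np.zeros(3)
    eps = 1e-12 * a
    for k in range(4):
        A = verts[k]
        B = verts[(k + 1) % 4]
        # p coinciding with a square corner makes the adjacent triangles
        # degenerate; they contribute nothing
        if np.hypot(*A) < eps or np.hypot(*B) < eps:
            continue
        cross = A[0] * B[1] - A[1] * B[0]
        dot = A @ B
        dtheta = np.arctan2(cross, dot)
        if dtheta == 0.0:
            continue
        theta = np.arctan2(A[1], A[0]) + tt * dtheta
        e = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        n_vec = np.array([B[1] - A[1], -(B[0] - A[0])])
        c = n_vec @ A
        denom = e @ n_vec
        R = c / denom  # distance from p to the edge line along e
        fac = pref * (
            (1.0 - nu) * np.array([1.0, 0.0, 1.0])[None, :]
            + nu * np.stack([e[:, 0] ** 2, e[:, 0] * e[:, 1], e[:, 1] ** 2], axis=1)
        )
        # radial integral of h along each ray
        rr = R[:, None] * rfrac[None, :]
        xs = p[0] + rr * e[:, 0:1]
        ys = p[1] + rr * e[:, 1:2]
        hv = _hat2(xs - node[0], ys - node[1], a)
        h_int = R * (hv @ rw)
        total += dtheta * np.einsum("q,qc,q->c", wt, fac, h_int)
    return total


def assemble_direct(sample_positions, grid: TractionGrid,
                    substrate: ElasticSubstrate,
                    quad_order: int = 6) -> ForwardOperator:
    """Reference assembly by per-entry numerical quadrature.

    Far entries use a tensor Gauss-Legendre rule on the four cells of each
    shape-function support; entries whose sample point lies inside or within
    half a mesh constant of the support use the singularity-free polar fan
    scheme.  Deterministic; intended as the slow oracle for the FFT routes.
    """
    if quad_order < 2:
        raise ValueError("quad_order must be >= 2")
    sample_positions = np.asarray(sample_positions, dtype=float)
    a = grid.mesh_constant
    nodes = grid.node_positions
    n = grid.n_nodes
    m = sample_positions.shape[0]
    # Gauss points on the reference support (4 cells around the node)
    t, w = leggauss(quad_order)
    t = 0.5 * (t + 1.0)
    w = 0.5 * w
    pts = []
    wts = []
    for sx in (-1.0, 0.0):
        for sy in (-1.0, 0.0):
            gx = (sx + t) * a
            gy = (sy + t) * a
            X, Y = np.meshgrid(gx, gy)
            W = np.outer(w, w) * a * a
            pts.append(np.column_stack([X.ravel(), Y.ravel()]))
            wts.append(W.ravel())
    ref_pts = np.concatenate(pts)
    ref_w = np.concatenate(wts)
    ref_h = _hat2(ref_pts[:, 0], ref_pts[:, 1], a)
    hw = ref_w * ref_h
    n_theta = 6 * quad_order
    n_r = 4 * quad_order
    M = np.empty((2 * m, 2 * n))
    for j in range(n):
        node = nodes[j]
        rel = sample_positions - node
        near = (np.abs(rel[:, 0]) < 1.5 * a) & (np.abs(rel[:, 1]) < 1.5 * a)
        far_idx = np.nonzero(~near)[0]
        if far_idx.size:
            qp = node + ref_pts
            dx = sample_positions[far_idx, 0:1] - qp[None, :, 0]
            dy = sample_positions[far_idx, 1:2] - qp[None, :, 1]
            gxx, gxy, gyy = greens_tensor_batch(dx, dy, substrate)
            exx = gxx @ hw
            exy = gxy @ hw
            eyy = gyy @ hw
            M[2 * far_idx, 2 * j] = exx
            M[2 * far_idx, 2 * j + 1] = exy
            M[2 * far_idx + 1, 2 * j] = exy
            M[2 * far_idx + 1, 2 * j + 1] = eyy
        for i in np.nonzero(near)[0]:
            exx, exy, eyy = _fan_entry(sample_positions[i], node, a, substrate,
                                       n_theta, n_r)
            M[2 * i, 2 * j] = exx
            M[2 * i, 2 * j + 1] = exy
            M[2 * i + 1, 2 * j] = exy
            M[2 * i + 1, 2 * j + 1] = eyy
    return ForwardOperator(
        matrix=M,
        source_grid=grid,
        target_positions=sample_positions,
        assembly_method="direct_quadrature",
        substrate=substrate,
        length_unit=grid.length_unit,
    )
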