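"""Synthetic traction scenes for benchmarking reconstruction quality.

The benchmark emulates the standard artificial-data protocol for traction
force microscopy: circular spots of uniform tangential traction on a
25 um x 25 um plane of a 10 kPa, nu = 0.3 gel, exact displacements from the
half-space solution, random sampling of the displacement field (fiducial
markers), and additive i.i.d. Gaussian noise.

The displacement of a uniformly loaded disc is computed semi-analytically:
in polar coordinates around the query point the product G(r e) * r depends
only on the direction e, so the radial integral over each chord through the
disc is exact and only an angular Gauss quadrature remains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss

from .grids import DisplacementField, TractionGrid
from .substrate import ElasticSubstrate

__all__ = [
    "Spot",
    "SpotScene",
    "NoiseSpec",
    "make_benchmark_scene",
    "analytic_displacement",
    "sample_displacements",
    "add_noise",
    "rasterize_traction",
]

DEFAULT_SUBSTRATE = ElasticSubstrate(youngs_modulus=10_000.0, poisson_ratio=0.3)
DEFAULT_DOMAIN = (25.0, 25.0)  # um
DEFAULT_SPOT_RADIUS = 1.0  # um (2 um diameter spots)
DEFAULT_PIXEL_SIZE = 0.1  # um per pixel

SCENE_VARIANTS = ("nine_spot_100Pa", "fifteen_spot_0_250Pa")


@dataclass(frozen=True)
class Spot:
    center: tuple[float, float]
    radius: float
    traction: tuple[float, float]  # Pa

    @property
    def magnitude(self) -> float:
        return float(np.hypot(*self.traction))


@dataclass
class SpotScene:
    """Ground-truth traction pattern: circular spots of uniform traction."""

    domain_size: tuple[float, float]
    spots: list[Spot]
    substrate: ElasticSubstrate = DEFAULT_SUBSTRATE
    length_unit: str = "um"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.spots:
            if s.radius <= 0:
                raise ValueError("spot radius must be > 0")
            cx, cy = s.center
            if not (0 <= cx <= self.domain_size[0] and 0 <= cy <= self.domain_size[1]):
                raise ValueError(f"spot center {s.center} outside domain")

    def to_json(self, path: str | None = None) -> str:
        rec = {
            "domain_size": list(self.domain_size),
            "length_unit": self.length_unit,
            "youngs_modulus": self.substrate.youngs_modulus,
            "poisson_ratio": self.substrate.poisson_ratio,
            "spots": [
                {"center": list(s.center), "radius": s.radius,
                 "traction": list(s.traction)}
                for s in self.spots
            ],
            "meta": self.meta,
        }
        text = json.dumps(rec, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "SpotScene":
        try:
            rec = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                rec = json.load(fh)
        return cls(
            domain_size=tuple(rec["domain_size"]),
            spots=[
                Spot(tuple(s["center"]), s["radius"], tuple(s["traction"]))
                for s in rec["spots"]
            ],
            substrate=ElasticSubstrate(rec["youngs_modulus"], rec["poisson_ratio"]),
            length_unit=rec.get("length_unit", "um"),
            meta=rec.get("meta", {}),
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian displacement noise.

    mode "percent_of_max": level is the noise standard deviation in percent
    of the largest true displacement magnitude.  mode "inverse_variance":
    level is beta = 1/sigma^2 in 1/length_unit^2 (the Bayesian convention).
    """

    mode: str
    level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("percent_of_max", "inverse_variance"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if not self.level > 0:
            raise ValueError("noise level must be > 0")

    def sigma(self, noise_free: np.ndarray | None = None) -> float:
        if self.mode == "inverse_variance":
            return 1.0 / np.sqrt(self.level)
        if noise_free is None:
            raise ValueError("percent_of_max mode requires the noise-free field")
        mags = np.linalg.norm(np.asarray(noise_free, dtype=float).reshape(-1, 2), axis=1)
        return self.level / 100.0 * float(mags.max())


def make_benchmark_scene(variant: str, seed: int = 0,
                         substrate: ElasticSubstrate = DEFAULT_SUBSTRATE,
                         domain_size: tuple[float, float] = DEFAULT_DOMAIN,
                         spot_radius: float = DEFAULT_SPOT_RADIUS) -> SpotScene:
    """Deterministic benchmark scene on the 25 um x 25 um plane.

    ``nine_spot_100Pa``: 9 spots, each 100 Pa.  ``fifteen_spot_0_250Pa``:
    15 spots with magnitudes evenly spaced over [0, 250] Pa and shuffled, so
    weak spots always exist.  Spot centers are rejection-sampled with at
    least one diameter of center separation (non-overlapping discs) and a
    margin to the domain edge; traction directions are uniform random.
    """
    if variant not in SCENE_VARIANTS:
        raise ValueError(f"variant must be one of {SCENE_VARIANTS}")
    rng = np.random.default_rng(seed)
    n_spots = 9 if variant == "nine_spot_100Pa" else 15
    if variant == "nine_spot_100Pa":
        mags = np.full(n_spots, 100.0)
    else:
        mags = np.linspace(0.0, 250.0, n_spots)
        rng.shuffle(mags)
    min_sep = 2.0 * (2.0 * spot_radius)  # one diameter between disc edges
    margin = 2.0 * spot_radius
    centers: list[np.ndarray] = []
    for _ in range(100_000):
        cand = np.array([
            rng.uniform(margin, domain_size[0] - margin),
            rng.uniform(margin, domain_size[1] - margin),
        ])
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
        if len(centers) == n_spots:
            break
    else:
        raise RuntimeError("could not place non-overlapping spots")
    angles = rng.uniform(0.0, 2.0 * np.pi, n_spots)
    spots = [
        Spot(
            center=(float(c[0]), float(c[1])),
            radius=spot_radius,
            traction=(float(m * np.cos(t)), float(m * np.sin(t))),
        )
        for c, m, t in zip(centers, mags, angles)
    ]
    return SpotScene(
        domain_size=domain_size,
        spots=spots,
        substrate=substrate,
        meta={"variant": variant, "seed": seed},
    )


def _disc_displacement(query: np.ndarray, center, radius, traction,
                       substrate: ElasticSubstrate, n_theta: int) -> np.ndarray:
    """Displacement (len(query), 2) from one uniformly loaded disc.

    u_i(p) = (1+nu)/(pi E) * integral d(theta)
             [(1-nu) delta_ij + nu e_i e_j] chord(p, theta) t_j
    where chord is the length of the ray-disc intersection.  Exact in the
    radial direction; Gauss-Legendre in the angle.
    """
    E = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    pref = (1.0 + nu) / (np.pi * E)
    t_vec = np.asarray(traction, dtype=float)
    d = np.asarray(center, dtype=float) - query  # (Q, 2) towards disc center
    rho = np.hypot(d[:, 0], d[:, 1])
    out = np.zeros((query.shape[0], 2))
    tg, wg = leggauss(n_theta)

    inside = rho < radius * (1.0 - 1e-12)
    for mask, full_circle in ((inside, True), (~inside, False)):
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        di = d[idx]
        ri = rho[idx]
        if full_circle:
            theta = np.pi * (tg + 1.0)  # [0, 2pi)
            w = np.pi * wg
            e = np.stack([np.cos(theta), np.sin(theta)])  # (2, T)
            dot = di @ e  # (Q, T)
            disc = dot * dot - (ri * ri - radius * radius)[:, None]
            chord = dot + np.sqrt(np.maximum(disc, 0.0))
            wq = np.broadcast_to(w, chord.shape)
            ex = np.broadcast_to(e[0], chord.shape)
            ey = np.broadcast_to(e[1], chord.shape)
        else:
            # angular cone subtended by the disc, centered on theta_c
            with np.errstate(invalid="ignore"):
                half = np.arcsin(np.minimum(radius / np.maximum(ri, radius), 1.0))
            theta_c = np.arctan2(di[:, 1], di[:, 0])
            phi = half[:, None] * tg[None, :]  # (Q, T)
            theta = theta_c[:, None] + phi
            wq = half[:, None] * wg[None, :]
            ex = np.cos(theta)
            ey = np.sin(theta)
            dot = di[:, 0:1] * ex + di[:, 1:2] * ey
            disc = dot * dot - (ri * ri - radius * radius)[:, None]
            chord = 2.0 * np.sqrt(np.maximum(disc, 0.0))
        cxx = (1.0 - nu) + nu * ex * ex
        cxy = nu * ex * ey
        cyy = (1.0 - nu) + nu * ey * ey
        wc = wq * chord
        out[idx, 0] += pref * ((wc * cxx).sum(axis=1) * t_vec[0]
                               + (wc * cxy).sum(axis=1) * t_vec[1])
        out[idx, 1] += pref * ((wc * cxy).sum(axis=1) * t_vec[0]
                               + (wc * cyy).sum(axis=1) * t_vec[1])
    return out


def analytic_displacement(scene: SpotScene, query_points,
                          n_theta: int = 256) -> np.ndarray:
    """Exact (to angular quadrature) displacements of the scene, (Q, 2)."""
    query = np.asarray(query_points, dtype=float)
    if query.ndim != 2 or query.shape[1] != 2:
        raise ValueError("query_points must have shape (Q, 2)")
    u = np.zeros_like(query)
    for spot in scene.spots:
        if spot.magnitude == 0.0:
            continue
        u += _disc_displacement(query, spot.center, spot.radius, spot.traction,
                                scene.substrate, n_theta)
    return u


def sample_displacements(scene: SpotScene, m: int, seed: int = 0,
                         n_theta: int = 256) -> DisplacementField:
    """Sample the displacement field at m uniform random positions."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    pos = np.column_stack([
        rng.uniform(0.0, scene.domain_size[0], m),
        rng.uniform(0.0, scene.domain_size[1], m),
    ])
    u = analytic_displacement(scene, pos, n_theta=n_theta)
    area = scene.domain_size[0] * scene.domain_size[1]
    return DisplacementField(
        positions=pos,
        vectors=u.ravel(),
        length_unit=scene.length_unit,
        meta={"seed": seed, "mean_spacing": float(np.sqrt(area / m))},
    )


def add_noise(u: DisplacementField, spec: NoiseSpec) -> DisplacementField:
    """Add i.i.d. zero-mean Gaussian noise to every displacement component.

    Records the realized sigma and the equivalent beta = 1/sigma^2 in the
    returned field's metadata.
    """
    sigma = spec.sigma(u.vectors)
    rng = np.random.default_rng(spec.seed)
    noisy = u.vectors + rng.normal(0.0, sigma, size=u.vectors.shape)
    meta = dict(u.meta)
    meta.update(
        noise_mode=spec.mode,
        noise_level=spec.level,
        noise_seed=spec.seed,
        noise_sigma=sigma,
        noise_beta=1.0 / sigma**2,
    )
    return DisplacementField(positions=u.positions.copy(), vectors=noisy,
                             length_unit=u.length_unit, meta=meta)


def rasterize_traction(scene: SpotScene, grid: TractionGrid,
                       antialias: bool = False) -> np.ndarray:
    """Ground-truth traction vector (2n,) on the grid.

    With ``antialias=False`` (default) a node carries the spot traction iff
    its position lies inside a disc (boundary inclusive) — the sharp ground
    truth used by the error metrics.  With ``antialias=True`` boundary nodes
    are weighted by the disc coverage fraction of their cell (16x16
    subsampling), which preserves the total force of the interpolated field
    and is appropriate when feeding the rasterized field through the forward
    operator.
    """
    pos = grid.node_positions
    a = grid.mesh_constant
    f = np.zeros((grid.n_nodes, 2))
    if antialias:
        k = 16
        off = (np.arange(k) + 0.5) / k - 0.5
        sx, sy = np.meshgrid(off * a, off * a)
        sub = np.column_stack([sx.ravel(), sy.ravel()])
    for spot in scene.spots:
        d = np.hypot(pos[:, 0] - spot.center[0], pos[:, 1] - spot.center[1])
        if not antialias:
            f[d <= spot.radius] = spot.traction
            continue
        maybe = d <= spot.radius + a
        pts = pos[maybe][:, None, :] + sub[None, :, :]
        rr = np.hypot(pts[..., 0] - spot.center[0], pts[..., 1] - spot.center[1])
        frac = (rr <= spot.radius).mean(axis=1)
        f[maybe] = frac[:, None] * np.asarray(spot.traction)
    return f.ravel()
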