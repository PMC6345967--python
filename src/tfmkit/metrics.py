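"""Reconstruction-quality metrics against a known ground truth.

Traction nodes are partitioned into circular traction patches and
background.  Four dimensionless measures compare reconstructed and real
traction magnitudes:

- DTMA: mean relative error of the per-patch mean magnitude (0 = perfect;
  negative = underestimation, positive = overestimation).
- DTMB: background magnitude error normalized by the mean patch magnitude
  (|DTMB| << 1 means a clean background).
- SNR: mean patch magnitude over the background standard deviation (>> 1
  means signal well separated from noise).
- DMA: mean relative error of the per-patch *peak* magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import TractionGrid
from .synthetic import SpotScene

__all__ = [
    "assign_patches",
    "ErrorReport",
    "dtma",
    "dtmb",
    "snr",
    "dma",
    "evaluate",
]

BACKGROUND = -1


def assign_patches(positions, scene: SpotScene) -> np.ndarray:
    """Label each traction node: patch index (0-based) or -1 for background.

    A node belongs to a patch when its position lies inside that spot's
    disc, boundary inclusive.
    """
    if isinstance(positions, TractionGrid):
        positions = positions.node_positions
    positions = np.asarray(positions, dtype=float)
    labels = np.full(positions.shape[0], BACKGROUND, dtype=int)
    for k, spot in enumerate(scene.spots):
        d = np.hypot(positions[:, 0] - spot.center[0],
                     positions[:, 1] - spot.center[1])
        labels[d <= spot.radius] = k
    return labels


def _magnitudes(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim == 1:
        t = t.reshape(-1, 2)
    return np.linalg.norm(t, axis=1)


def _patch_ids(labels, real_mag=None, need_nonzero=False, metric=""):
    ids = [k for k in np.unique(labels) if k != BACKGROUND]
    if not ids:
        raise ValueError("assignment contains no patches")
    if need_nonzero:
        kept = []
        for k in ids:
            if real_mag[labels == k].mean() > 0:
                kept.append(k)
            else:
                warnings.warn(f"{metric}: patch {k} has zero real traction; excluded")
        ids = kept
        if not ids:
            raise ValueError("all patches have zero real traction")
    return ids


def dtma(recon, real, assignment) -> float:
    """Deviation of traction magnitude at adhesions."""
    labels = np.asarray(assignment)
    rec = _magnitudes(recon)
    tru = _magnitudes(real)
    ids = _patch_ids(labels, tru, need_nonzero=True, metric="DTMA")
    terms = []
    for k in ids:
        sel = labels == k
        terms.append((rec[sel].mean() - tru[sel].mean()) / tru[sel].mean())
    return float(np.mean(terms))


def dtmb(recon, real, assignment) -> float:
    """Deviation of traction magnitude in the background."""
    labels = np.asarray(assignment)
    rec = _magnitudes(recon)
    tru = _magnitudes(real)
    bg = labels == BACKGROUND
    if not bg.any():
        raise ValueError("assignment has an empty background")
    ids = _patch_ids(labels, tru, need_nonzero=True, metric="DTMB")
    patch_mean = np.mean([tru[labels == k].mean() for k in ids])
    return float((rec[bg].mean() - tru[bg].mean()) / patch_mean)


def snr(recon, assignment, background_std: str = "components") -> float:
    """Signal-to-noise ratio of the reconstruction.

    The numerator is the mean over patches of the mean reconstructed patch
    magnitude.  The denominator is the standard deviation of the background
    traction, by default over all 2 x (background count) vector components
    (set ``background_std="magnitudes"`` for the std of magnitudes).
    Returns +inf when the background is exactly constant.
    """
    labels = np.asarray(assignment)
    t = np.asarray(recon, dtype=float).reshape(-1, 2)
    rec = np.linalg.norm(t, axis=1)
    bg = labels == BACKGROUND
    if bg.sum() < 2:
        raise ValueError("need at least 2 background nodes")
    ids = _patch_ids(labels)
    signal = np.mean([rec[labels == k].mean() for k in ids])
    if background_std == "components":
        comp = t[bg].ravel()
        noise = float(comp.std(ddof=1))
    elif background_std == "magnitudes":
        noise = float(rec[bg].std(ddof=1))
    else:
        raise ValueError("background_std must be 'components' or 'magnitudes'")
    if noise == 0.0:
        return float("inf")
    return float(signal / noise)


def dma(recon, real, assignment) -> float:
    """Deviation of the traction maximum at adhesions."""
    labels = np.asarray(assignment)
    rec = _magnitudes(recon)
    tru = _magnitudes(real)
    ids = [k for k in np.unique(labels) if k != BACKGROUND]
    terms = []
    for k in ids:
        sel = labels == k
        peak = tru[sel].max()
        if peak == 0:
            warnings.warn(f"DMA: patch {k} has zero real maximum; excluded")
            continue
        terms.append((rec[sel].max() - peak) / peak)
    if not terms:
        raise ValueError("all patches have zero real maxima")
    return float(np.mean(terms))


@dataclass
class ErrorReport:
    dtma: float
    dtmb: float
    snr: float
    dma: float

    def to_text(self) -> str:
        return "".join(f"{k} = {v:.6g}\n" for k, v in vars(self).items())


def evaluate(recon, real, assignment) -> ErrorReport:
    """All four metrics in one report."""
    return ErrorReport(
        dtma=dtma(recon, real, assignment),
        dtmb=dtmb(recon, real, assignment),
        snr=snr(recon, assignment),
        dma=dma(recon, real, assignment),
    )
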