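"""Perceptual-space embeddings whose Euclidean distances reproduce the
receptor-noise-limited JND distances.

The chromatic embedding whitens centered log-catches with the metric of the
noise-limited distance, giving exact (n_receptors - 1)-dimensional
coordinates. Orientation is fixed by convention: axis 1 is aligned with the
long-wavelength-vs-rest opponent direction, with the reddest stimulus (the
one with the largest long-wavelength log-catch excess) positive on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contrasts import QuantumCatches, _check_positive
from .visual import VisualSystem


@dataclass
class PerceptualCoordinates:
    labels: list[str]
    coords: np.ndarray  # (n_stimuli, n_receptors - 1), JND units
    lum: np.ndarray | None  # (n_stimuli,), JND units, centered
    system: str

    def to_frame(self) -> pd.DataFrame:
        axes = {f"x{i + 1}": self.coords[:, i] for i in range(self.coords.shape[1])}
        data = {"label": self.labels, **axes}
        if self.lum is not None:
            data["lum"] = self.lum
        return pd.DataFrame(data)


def _rnl_metric(e: np.ndarray) -> np.ndarray:
    """PSD matrix M with df' M df = deltaS^2 (rank n-1)."""
    d = 1.0 / e**2
    return np.diag(d) - np.outer(d, d) / d.sum()


def _whitener(system: VisualSystem) -> np.ndarray:
    """(n-1, n) map W with ||W df|| = deltaS; errors on a degenerate metric."""
    e = system.noise()
    n = len(e)
    M = _rnl_metric(e)
    vals, vecs = np.linalg.eigh(M)
    # expect exactly one (near-)zero eigenvalue: the achromatic direction
    tol = 1e-9 * vals.max()
    if np.sum(vals < tol) != 1:
        raise ValueError("degenerate receptor-noise metric (duplicate receptors?)")
    keep = vals >= tol
    W = (np.sqrt(vals[keep])[:, None] * vecs[:, keep].T)[::-1]  # descending eigenvalue order
    return W


def _orientation(system: VisualSystem, W: np.ndarray) -> np.ndarray:
    """Orthonormal basis whose first axis is the image of the long-wavelength
    opponent direction under the whitening map."""
    n = system.n_receptors
    lws = int(np.argmax([r.lambda_max for r in system.receptors]))
    v = np.full(n, -1.0 / (n - 1))
    v[lws] = 1.0
    u = W @ v
    u = u / np.linalg.norm(u)
    # complete to an orthonormal basis (columns), first column = u
    k = W.shape[0]
    B = np.eye(k)
    B[:, 0] = u
    Q, _ = np.linalg.qr(B)
    # qr may flip the first column's sign; force Q[:,0] == u
    if np.dot(Q[:, 0], u) < 0:
        Q[:, 0] *= -1.0
    return Q


def jnd_coordinates(
    catches: list[QuantumCatches], system: VisualSystem
) -> PerceptualCoordinates:
    """Exact chromatic coordinates: pairwise Euclidean distance == deltaS."""
    if len(catches) < 2:
        raise ValueError("need at least 2 stimuli")
    for q in catches:
        _check_positive(q, system)
        if q.system != system.name:
            raise ValueError("catches computed under a different system")
    F = np.log(np.stack([q.raw for q in catches]))  # (n_stimuli, n_receptors)
    Fc = F - F.mean(axis=0)
    W = _whitener(system)
    X = Fc @ W.T
    B = _orientation(system, W)
    X = X @ B
    # sign conventions: reddest stimulus positive on axis 1; remaining axes
    # have their largest-magnitude entry positive
    lws = int(np.argmax([r.lambda_max for r in system.receptors]))
    reddest = int(np.argmax(Fc[:, lws] - Fc.mean(axis=1)))
    if X[reddest, 0] < 0:
        X[:, 0] *= -1.0
    for j in range(1, X.shape[1]):
        i = int(np.argmax(np.abs(X[:, j])))
        if X[i, j] < 0:
            X[:, j] *= -1.0
    lum = _luminance_axis(catches, system)
    return PerceptualCoordinates(
        labels=[q.label for q in catches], coords=X, lum=lum, system=system.name
    )


def _luminance_axis(catches: list[QuantumCatches], system: VisualSystem) -> np.ndarray | None:
    ql = np.array([q.luminance for q in catches])
    if np.any(ql <= 0):
        return None
    lum = np.log(ql) / system.weber_luminance
    return lum - lum.mean()


def crab_plane(catches: list[QuantumCatches], system: VisualSystem) -> PerceptualCoordinates:
    """Dichromat plane: x = signed chromatic coordinate (long-wavelength-
    dominated stimuli to the left, short-wavelength to the right), y =
    centered luminance coordinate ln(Q_L)/Weber. |dx| equals deltaS.
    """
    if system.n_receptors != 2:
        raise ValueError("crab_plane requires a dichromatic system")
    for q in catches:
        _check_positive(q, system)
    lmaxes = [r.lambda_max for r in system.receptors]
    i_lws = int(np.argmax(lmaxes))
    i_sws = 1 - i_lws
    e = system.noise()
    F = np.log(np.stack([q.raw for q in catches]))
    x = (F[:, i_sws] - F[:, i_lws]) / np.sqrt(e[0] ** 2 + e[1] ** 2)
    x = x - x.mean()
    lum = _luminance_axis(catches, system)
    return PerceptualCoordinates(
        labels=[q.label for q in catches], coords=x[:, None], lum=lum, system=system.name
    )
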