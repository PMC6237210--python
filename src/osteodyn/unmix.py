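"""Linear spectral unmixing by per-pixel nonnegative least squares.

Multi-detector two-photon images mix the true fluorophore signals with
tissue autofluorescence. Given reference spectra (one column per
endmember, one of which is the autofluorescence component), each pixel's
detector vector is decomposed into nonnegative endmember abundances by
solving ``min ||S·a - x||₂, a ≥ 0``; discarding the autofluorescence
abundance yields cleaned channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .stack import ImageStack

__all__ = ["EndmemberMatrix", "unmix", "load_endmembers", "save_endmembers"]

#: Columns with condition number above this are rejected as rank-deficient.
MAX_CONDITION = 1e8


@dataclass
class EndmemberMatrix:
    """Reference spectra: detector-channels × endmembers, all nonnegative."""

    spectra: np.ndarray
    endmember_names: list[str]

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D (detectors × endmembers) matrix")
        if self.spectra.shape[1] != len(self.endmember_names):
            raise ValueError(
                f"{self.spectra.shape[1]} spectra but "
                f"{len(self.endmember_names)} names"
            )
        if np.any(self.spectra < 0):
            raise ValueError("endmember spectra must be nonnegative")
        norms = np.linalg.norm(self.spectra, axis=0)
        if np.any(norms == 0):
            zero = [self.endmember_names[i] for i in np.flatnonzero(norms == 0)]
            raise ValueError(f"endmember(s) with zero spectrum: {zero}")
        cond = np.linalg.cond(self.spectra)
        if not np.isfinite(cond) or cond > MAX_CONDITION:
            raise ValueError(
                f"endmember matrix is rank-deficient or ill-conditioned "
                f"(condition number {cond:.3g} > {MAX_CONDITION:.0e}); "
                f"spectra must be linearly independent"
            )

    @property
    def n_detectors(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_endmembers(self) -> int:
        return self.spectra.shape[1]


def _nnls_pixels(S: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Solve min ||S a - x||, a >= 0 for every column x of X (D × N).

    Fast path: the unconstrained least-squares solution; pixels where it
    goes negative are re-solved with Lawson–Hanson NNLS.
    """
    sol, *_ = np.linalg.lstsq(S, X, rcond=None)
    bad = np.flatnonzero((sol < -1e-12).any(axis=0))
    for j in bad:
        sol[:, j], _ = nnls(S, X[:, j])
    np.clip(sol, 0.0, None, out=sol)
    return sol


def unmix(raw: ImageStack, endmembers: EndmemberMatrix) -> ImageStack:
    """Unmix a raw detector stack into per-endmember abundance maps.

    Returns an :class:`ImageStack` whose channels are the endmember names
    in order (including ``autofluorescence``); all abundances are ≥ 0.
    """
    if raw.data.shape[1] != endmembers.n_detectors:
        raise ValueError(
            f"raw stack has {raw.data.shape[1]} detector channels but the "
            f"endmember matrix expects {endmembers.n_detectors}"
        )
    T, D, ny, nx = raw.data.shape
    X = raw.data.transpose(1, 0, 2, 3).reshape(D, -1)
    A = _nnls_pixels(endmembers.spectra, X)
    out = A.reshape(endmembers.n_endmembers, T, ny, nx).transpose(1, 0, 2, 3)
    return ImageStack(out, list(endmembers.endmember_names),
                      pixel_size=raw.pixel_size,
                      frame_interval=raw.frame_interval)


def save_endmembers(endmembers: EndmemberMatrix, path: str | Path) -> None:
    """Write spectra as CSV: rows = detector channels, columns = endmembers."""
    pd.DataFrame(endmembers.spectra, columns=endmembers.endmember_names).to_csv(
        path, index=False
    )


def load_endmembers(path: str | Path) -> EndmemberMatrix:
    df = pd.read_csv(path)
    return EndmemberMatrix(df.to_numpy(dtype=float), list(df.columns))
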