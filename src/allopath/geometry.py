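"""Least-squares superposition utilities (Kabsch algorithm)."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_rotation", "superpose", "superpose_frames", "rmsd"]


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray,
                    weights: np.ndarray | None = None) -> np.ndarray:
    """Optimal rotation matrix mapping centered ``mobile`` onto ``reference``."""
    if weights is None:
        weights = np.ones(len(mobile))
    w = weights / weights.sum()
    H = (mobile * w[:, None]).T @ reference
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None) -> np.ndarray:
    """Rigid-body fit of ``mobile`` onto ``reference`` (rotation+translation)."""
    if weights is None:
        weights = np.ones(len(mobile))
    w = weights / weights.sum()
    mob_c = (mobile * w[:, None]).sum(axis=0)
    ref_c = (reference * w[:, None]).sum(axis=0)
    R = kabsch_rotation(mobile - mob_c, reference - ref_c, weights)
    return (mobile - mob_c) @ R.T + ref_c


def superpose_frames(coords: np.ndarray, fit_indices: np.ndarray | None = None,
                     weights: np.ndarray | None = None,
                     n_iter: int = 2) -> np.ndarray:
    """Fit every frame onto the iteratively refined mean structure.

    ``coords`` has shape (n_frames, n_atoms, 3); the fit is computed on
    ``fit_indices`` (default: all atoms) and applied to all atoms.
    """
    coords = np.array(coords, dtype=float, copy=True)
    if fit_indices is None:
        fit_indices = np.arange(coords.shape[1])
    ref = coords[0, fit_indices]
    for _ in range(n_iter):
        for t in range(coords.shape[0]):
            mob = coords[t, fit_indices]
            if weights is None:
                w = np.ones(len(mob))
            else:
                w = weights
            wn = w / w.sum()
            mob_c = (mob * wn[:, None]).sum(axis=0)
            ref_c = (ref * wn[:, None]).sum(axis=0)
            R = kabsch_rotation(mob - mob_c, ref - ref_c, w)
            coords[t] = (coords[t] - mob_c) @ R.T + ref_c
        ref = coords[:, fit_indices].mean(axis=0)
    return coords


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without refitting."""
    return float(np.sqrt(np.mean(np.sum((np.asarray(a) - np.asarray(b)) ** 2,
                                        axis=-1))))
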