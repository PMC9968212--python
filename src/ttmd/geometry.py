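"""Rigid-body superposition (Kabsch) and RMSD helpers."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["superpose_kabsch", "rmsd"]


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unfitted) root-mean-square deviation between coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must have the same shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose_kabsch(mobile: np.ndarray, target: np.ndarray, subset=None):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, fitted_rmsd)`` where the fit minimises
    the RMSD over ``subset`` (all atoms if None) and the transform maps
    mobile coordinates as ``coords @ rotation.T + translation``.  The
    rotation is always proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("mobile and target must have the same shape")
    sel_m = mobile if subset is None else mobile[subset]
    sel_t = target if subset is None else target[subset]
    if len(sel_m) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    cm, ct = sel_m.mean(axis=0), sel_t.mean(axis=0)
    # scipy's align_vectors implements the Kabsch solution (proper rotation)
    rot, _ = Rotation.align_vectors(sel_t - ct, sel_m - cm)
    if len(sel_m) >= 3 and np.linalg.matrix_rank(sel_m - cm) < 2:
        raise ValueError("degenerate (collinear) atom subset")
    R = rot.as_matrix()
    t = ct - cm @ R.T
    fitted = rmsd(sel_m @ R.T + t, sel_t)
    return R, t, fitted
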