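"""Rigid-body superposition (Kabsch) and RMSD.

Closed-form least-squares alignment of paired point sets restricted to
proper rotations (determinant +1), so mirror images are never matched onto
each other. Used by the pharmacophore matcher and by binding-site
comparison.
"""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation + translation mapping ``mobile`` onto ``target``.

    Parameters
    ----------
    mobile, target:
        ``(n, 3)`` arrays of paired coordinates, ``n >= 1``.

    Returns
    -------
    rotation : (3, 3) ndarray
        Proper rotation matrix (``det = +1``).
    translation : (3,) ndarray
        Applied as ``x @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (mobile - mu_m).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    # flip the smallest singular direction if the optimum is a reflection
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = mu_t - rot @ mu_m
    return rot, trans


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply ``x -> R x + t`` to an ``(n, 3)`` coordinate array."""
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation


def superpose_rmsd(mobile: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Superpose ``mobile`` onto ``target`` and return ``(rmsd, rotation, translation)``."""
    rot, trans = kabsch(mobile, target)
    moved = apply_transform(mobile, rot, trans)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - np.asarray(target, float)) ** 2, axis=1))))
    return rmsd, rot, trans


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
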