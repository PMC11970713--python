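"""Vectorized geometric primitives: distances, angles, torsions, superposition.

All routines operate on (n, 3) coordinate arrays and index arrays, and the
energy-related ones return analytic gradients, accumulated by scatter-add,
so the annealer can run on plain L-BFGS.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-10


def _scatter(grad: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """grad[idx] += vals via bincount (much faster than np.add.at)."""
    n = grad.shape[0]
    for k in range(3):
        grad[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)


def pair_distances(x: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    d = x[i] - x[j]
    return np.sqrt(np.sum(d * d, axis=1))


def harmonic_pair_energy(x, i, j, r0, k, grad):
    """sum k (|xi-xj| - r0)^2 with gradient accumulation; returns energy."""
    d = x[i] - x[j]
    r = np.sqrt(np.sum(d * d, axis=1))
    r_safe = np.maximum(r, _EPS)
    dev = r - r0
    e = float(np.sum(k * dev * dev))
    coef = (2.0 * k * dev / r_safe)[:, None]
    g = coef * d
    _scatter(grad, i, g)
    _scatter(grad, j, -g)
    return e


def angles(x, i, j, k):
    """Angle at vertex j for each (i, j, k) triple, radians."""
    u = x[i] - x[j]
    v = x[k] - x[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.sum(u * v, axis=1) / np.maximum(nu * nv, _EPS)
    return np.arccos(np.clip(c, -1.0, 1.0))


def harmonic_angle_energy(x, i, j, k, theta0, kf, grad):
    """sum kf (theta - theta0)^2, theta0 in radians; returns energy."""
    u = x[i] - x[j]
    v = x[k] - x[j]
    nu = np.maximum(np.linalg.norm(u, axis=1), _EPS)
    nv = np.maximum(np.linalg.norm(v, axis=1), _EPS)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
    theta = np.arccos(c)
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-8))
    dev = theta - theta0
    e = float(np.sum(kf * dev * dev))
    # dtheta/du = (c*uh - vh) / (|u| * s)
    pref = (2.0 * kf * dev)[:, None]
    gi = pref * (c[:, None] * uh - vh) / (nu * s)[:, None]
    gk = pref * (c[:, None] * vh - uh) / (nv * s)[:, None]
    _scatter(grad, i, gi)
    _scatter(grad, k, gk)
    _scatter(grad, j, -(gi + gk))
    return e


def torsions(x, a, b, c, d):
    """Signed dihedral for each (a, b, c, d) quadruple, radians in (-pi, pi]."""
    b1 = x[b] - x[a]
    b2 = x[c] - x[b]
    b3 = x[d] - x[c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.maximum(np.linalg.norm(b2, axis=1), _EPS)
    m1 = np.cross(n1, b2 / nb2[:, None])
    xcomp = np.sum(n1 * n2, axis=1)
    ycomp = np.sum(m1 * n2, axis=1)
    return np.arctan2(ycomp, xcomp)


def _torsion_grads(x, a, b, c, d):
    """Analytic dphi/dx for each quadruple (standard rigid-rotation identities)."""
    b1 = x[b] - x[a]
    b2 = x[c] - x[b]
    b3 = x[d] - x[c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.maximum(np.linalg.norm(b2, axis=1), _EPS)
    n1sq = np.maximum(np.sum(n1 * n1, axis=1), _EPS)
    n2sq = np.maximum(np.sum(n2 * n2, axis=1), _EPS)
    ga = (-nb2 / n1sq)[:, None] * n1
    gd = (nb2 / n2sq)[:, None] * n2
    s12 = (np.sum(b1 * b2, axis=1) / (nb2 * nb2))[:, None]
    s32 = (np.sum(b3 * b2, axis=1) / (nb2 * nb2))[:, None]
    gb = -ga + s12 * ga - s32 * gd
    gc = -gd - s12 * ga + s32 * gd
    return ga, gb, gc, gd


def wrap_angle(phi):
    """Wrap to (-pi, pi]."""
    return np.mod(phi + np.pi, 2.0 * np.pi) - np.pi


def torsion_well_energy(x, a, b, c, d, target, halfwidth, kf, grad):
    """Flat-well torsion energy: zero within +-halfwidth of target (radians)."""
    phi = torsions(x, a, b, c, d)
    dev = wrap_angle(phi - target)
    excess = np.sign(dev) * np.maximum(np.abs(dev) - halfwidth, 0.0)
    e = float(np.sum(kf * excess * excess))
    if e > 0.0:
        coef = (2.0 * kf * excess)[:, None]
        ga, gb, gc, gd = _torsion_grads(x, a, b, c, d)
        _scatter(grad, a, coef * ga)
        _scatter(grad, b, coef * gb)
        _scatter(grad, c, coef * gc)
        _scatter(grad, d, coef * gd)
    return e


def torsion_cos_energy(x, a, b, c, d, kf, grad, trans=True):
    """kf (1 +- cos phi): minimized with zero slope at pi (trans) or 0 (cis)."""
    phi = torsions(x, a, b, c, d)
    sgn = 1.0 if trans else -1.0
    e = float(np.sum(kf * (1.0 + sgn * np.cos(phi))))
    coef = (-sgn * kf * np.sin(phi))[:, None]
    ga, gb, gc, gd = _torsion_grads(x, a, b, c, d)
    _scatter(grad, a, coef * ga)
    _scatter(grad, b, coef * gb)
    _scatter(grad, c, coef * gc)
    _scatter(grad, d, coef * gd)
    return e


def chirality_energy(x, center, p1, p2, p3, v0, kf, grad):
    """Harmonic on the scalar triple product (p1-c)·((p2-c)×(p3-c)).

    Enforces the hand of the CA center; v0 is the ideal signed volume.
    """
    u = x[p1] - x[center]
    v = x[p2] - x[center]
    w = x[p3] - x[center]
    cvw = np.cross(v, w)
    vol = np.sum(u * cvw, axis=1)
    dev = vol - v0
    e = float(np.sum(kf * dev * dev))
    pref = (2.0 * kf * dev)[:, None]
    gu = pref * cvw
    gv = pref * np.cross(w, u)
    gw = pref * np.cross(u, v)
    _scatter(grad, p1, gu)
    _scatter(grad, p2, gv)
    _scatter(grad, p3, gw)
    _scatter(grad, center, -(gu + gv + gw))
    return e


def repulsion_energy(x, i, j, rmin, kf, grad):
    """Soft-sphere: kf (rmin - r)^2 for r < rmin, pairwise."""
    d = x[i] - x[j]
    r = np.sqrt(np.sum(d * d, axis=1))
    mask = r < rmin
    if not np.any(mask):
        return 0.0
    im, jm, rm = i[mask], j[mask], np.maximum(r[mask], _EPS)
    dev = rmin[mask] - rm
    e = float(kf * np.sum(dev * dev))
    coef = (-2.0 * kf * dev / rm)[:, None]
    g = coef * d[mask]
    _scatter(grad, im, g)
    _scatter(grad, jm, -g)
    return e


def kabsch(p: np.ndarray, q: np.ndarray):
    """Optimal rotation R and translation t minimizing |R q + t - p|.

    Returns (R, t, rmsd).  Proper rotation (det +1) is enforced.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if p.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    p0 = p - pc
    q0 = q - qc
    h = q0.T @ p0
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    dmat = np.diag([1.0, 1.0, sign])
    r = vt.T @ dmat @ u.T
    t = pc - r @ qc
    diff = (q0 @ r.T) - p0
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return r, t, rmsd
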