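"""Shared fixtures and independent oracles for the test-suite."""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_intersect(scene, origin, direction, eps=1e-6):
    """Scalar all-primitive nearest-hit scan: the intersection oracle.

    Independent of the package's vectorised kernel: plain Python loop,
    plane + local-coordinate solve per primitive.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    best = (-1, np.inf, 0)
    for j, p in enumerate(scene.primitives):
        e1, e2 = p.edges
        n = p.normal
        dn = float(np.dot(direction, n))
        if abs(dn) < 1e-12:
            continue
        t = float(np.dot(p.vertices[0] - origin, n) / dn)
        if t <= eps:
            continue
        q = origin + t * direction
        pv = q - p.vertices[0]
        gram = np.array([[e1 @ e1, e1 @ e2], [e1 @ e2, e2 @ e2]])
        al, be = np.linalg.solve(gram, [pv @ e1, pv @ e2])
        tol = 1e-9
        if p.kind == "triangle":
            if not (al >= -tol and be >= -tol and al + be <= 1 + tol):
                continue
        else:
            if not (-tol <= al <= 1 + tol and -tol <= be <= 1 + tol):
                continue
            if p.texture_mask is not None:
                m = p.texture_mask
                iu = min(int(al * m.shape[0]), m.shape[0] - 1)
                iv = min(int(be * m.shape[1]), m.shape[1] - 1)
                if not m[iu, iv]:
                    continue
        if t < best[1]:
            best = (j, t, int(dn > 0))
    return best


@pytest.fixture
def intersection_oracle():
    return brute_force_intersect
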