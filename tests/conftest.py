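import numpy as np
import pytest

from acam.cortex import CortexLoop
from acam.tissue import Params, Tissue


def circle_loop(n=64, R=3.0, kappa=0.05, gamma=1.0, center=(0.0, 0.0)):
    ang = 2 * np.pi * np.arange(n) / n
    x = np.asarray(center) + R * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    d = np.hypot(*np.diff(np.vstack([x, x[:1]]), axis=0).T)
    return CortexLoop(1, x, d.copy(), np.full(n, gamma), kappa)


def open_rod(n=11, length=10.0, kappa=0.05, gamma=1.0, y=0.0):
    x = np.stack([np.linspace(0, length, n), np.full(n, y)], axis=1)
    d = np.full(n - 1, length / (n - 1))
    return CortexLoop(1, x, d, np.full(n - 1, gamma), kappa, closed=False)


def square_loop(cell_id, center, side=4.0, spacing=0.4, kappa=0.01):
    """Axis-aligned square cortex loop, counter-clockwise."""
    m = max(2, int(round(side / spacing)))
    s = side / m
    c = np.asarray(center, float)
    pts = []
    for k in range(m):
        pts.append([k * s, 0.0])
    for k in range(m):
        pts.append([side, k * s])
    for k in range(m):
        pts.append([side - k * s, side])
    for k in range(m):
        pts.append([0.0, side - k * s])
    x = np.array(pts) + c - side / 2.0
    d = np.hypot(*np.diff(np.vstack([x, x[:1]]), axis=0).T)
    return CortexLoop(cell_id, x, d.copy(), np.ones(len(d)), kappa)


def two_square_tissue(gap=1.0, side=4.0, spacing=0.4, **params):
    """Two square cells side by side, cortices ``gap`` apart."""
    p = Params(mesh_spacing=spacing, **params)
    l1 = square_loop(1, (0.0, 0.0), side, spacing)
    l2 = square_loop(2, (side + gap, 0.0), side, spacing)
    for lp in (l1, l2):
        lp.area0 = lp.area()
    return Tissue(loops=[l1, l2], params=p)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
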