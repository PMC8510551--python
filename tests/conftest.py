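"""Shared fixtures: analytic contours and small spacer libraries."""

import numpy as np
import pandas as pd
import pytest

from phenoscreen.fitness import SpacerLibrary
from phenoscreen.morphology import CellContour
from phenoscreen.simulate import spherocylinder_contour


@pytest.fixture
def sphero_4x1():
    """Spherocylinder contour, pole-to-pole length 4 um, width 1 um."""
    return CellContour("sphero", spherocylinder_contour(4.0, 1.0, 256))


@pytest.fixture
def circle_contour():
    """Degenerate rod (length == width): a circle of diameter 1 um."""
    return CellContour("circle", spherocylinder_contour(1.0, 1.0, 128))


def make_banana(radius: float = 5.0, width: float = 1.0,
                half_angle: float = np.pi / 6, n_arc: int = 200) -> CellContour:
    """Bent rod of constant width: a tube around a circular centerline arc,
    closed with semicircular caps. Centerline arc length = radius * 2 * half_angle."""
    th = np.linspace(-half_angle, half_angle, n_arc)
    r = width / 2.0
    outer = np.column_stack([(radius + r) * np.sin(th), (radius + r) * np.cos(th)])
    inner = np.column_stack([(radius - r) * np.sin(th),
                             (radius - r) * np.cos(th)])[::-1]

    def cap(t_end, sign, reverse=False):
        cx, cy = radius * np.sin(t_end), radius * np.cos(t_end)
        tx, ty = np.cos(t_end), -np.sin(t_end)       # centerline tangent
        nx, ny = np.sin(t_end), np.cos(t_end)        # radial normal
        phis = np.linspace(0, np.pi, 30)[1:-1]
        if reverse:
            phis = phis[::-1]
        pts = [(cx + np.cos(p) * nx * r + np.sin(p) * tx * r * sign,
                cy + np.cos(p) * ny * r + np.sin(p) * ty * r * sign)
               for p in phis]
        return np.array(pts)

    verts = np.vstack([outer, cap(th[-1], +1), inner, cap(th[0], -1, reverse=True)])
    return CellContour("banana", verts)


def make_dumbbell(lobe_width: float = 1.0, neck_width: float = 0.5,
                  half_length: float = 2.0, neck_sigma: float = 0.35) -> CellContour:
    """Deeply constricted dividing cell: two rod lobes joined by a narrow
    septal neck (Gaussian width dip), semicircular end caps."""
    def profile(x):
        dip = (lobe_width - neck_width) * np.exp(-(x / neck_sigma) ** 2)
        return lobe_width - dip

    xs = np.linspace(-half_length, half_length, 150)
    top = np.column_stack([xs, profile(xs) / 2])
    bot = np.column_stack([xs, -profile(xs) / 2])[::-1]
    r = lobe_width / 2.0
    phis = np.linspace(np.pi / 2, -np.pi / 2, 22)[1:-1]
    cap_r = np.column_stack([half_length + r * np.cos(phis), -r * np.sin(phis)])
    cap_l = np.column_stack([-half_length - r * np.cos(phis), r * np.sin(phis)])
    verts = np.vstack([top, cap_r[::-1], bot, cap_l[::-1]])
    return CellContour("dumbbell", verts)


@pytest.fixture
def banana_contour():
    return make_banana()


@pytest.fixture
def dumbbell_contour():
    return make_dumbbell()


@pytest.fixture
def tiny_library():
    """Four-strain library: two targeting strains, two nontargeting controls."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    spacers = ["".join(rng.choice(bases, 20)) for _ in range(4)]
    return SpacerLibrary(pd.DataFrame({
        "strain_id": ["sA", "sB", "c1", "c2"],
        "spacer": spacers,
        "gene": ["geneA", "geneB", "ctrl1", "ctrl2"],
        "category": ["essential", "nonessential", "control", "control"],
    }))
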