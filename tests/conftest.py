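"""Shared fixtures and the independent real-space Boussinesq oracle."""

from __future__ import annotations

import numpy as np
import pytest

from mechq.tfm import ElasticSubstrate


@pytest.fixture
def substrate() -> ElasticSubstrate:
    """Soft substrate typical of traction assays (1 kPa, nearly incompressible)."""
    return ElasticSubstrate(young_modulus_Pa=1000.0, poisson_ratio=0.45)


def boussinesq_quadrature(
    tx: np.ndarray,
    ty: np.ndarray,
    grid_spacing_um: float,
    substrate: ElasticSubstrate,
    probes_um: np.ndarray,
    subdiv: int = 6,
    traction_fn=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct real-space quadrature of the Boussinesq surface integral.

    Independent of any Fourier machinery: the field area (cells centred
    on the grid nodes) is subdivided ``subdiv x subdiv`` per cell and
    the tangential point-force Green's function

        G(r) = (1+nu) / (pi E r^3) * [[(1-nu) r^2 + nu x^2, nu x y],
                                      [nu x y, (1-nu) r^2 + nu y^2]]

    is summed midpoint-rule over all subcells.  When ``traction_fn`` is
    given (mapping ``(x_um, y_um) -> (tx, ty)``, e.g. an analytic patch
    description) the integrand uses the continuous traction at each
    subcell centre; otherwise the grid sample of the containing cell.
    Probe points must not coincide with subcell centres (the kernel is
    singular at r = 0); offsets of a fraction of a cell suffice.
    """
    e, nu = substrate.young_modulus_Pa, substrate.poisson_ratio
    d = grid_spacing_um
    ny, nx = tx.shape
    offsets = (np.arange(subdiv) + 0.5) / subdiv * d - d / 2
    cy, cx = np.mgrid[0:ny, 0:nx]
    xs0 = cx.ravel() * d
    ys0 = cy.ravel() * d
    sub_area = (d / subdiv) ** 2
    ux = np.zeros(len(probes_um))
    uy = np.zeros(len(probes_um))
    for oy in offsets:
        for ox in offsets:
            xs = xs0 + ox
            ys = ys0 + oy
            if traction_fn is None:
                t1, t2 = tx.ravel(), ty.ravel()
            else:
                t1, t2 = traction_fn(xs, ys)
            for i, (px, py) in enumerate(probes_um):
                rx = px - xs
                ry = py - ys
                r = np.hypot(rx, ry)
                r = np.where(r == 0, np.inf, r)
                pref = (1 + nu) / (np.pi * e * r**3)
                g11 = pref * ((1 - nu) * r**2 + nu * rx**2)
                g22 = pref * ((1 - nu) * r**2 + nu * ry**2)
                g12 = pref * nu * rx * ry
                ux[i] += np.sum(g11 * t1 + g12 * t2) * sub_area
                uy[i] += np.sum(g12 * t1 + g22 * t2) * sub_area
    return ux, uy
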