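"""Trivariate polynomial basis used for background-phase modelling.

Eddy-current background phase offsets in phase-contrast MRI are smooth,
slowly varying functions of space; they are modelled here as a full
trivariate polynomial of total degree 4 (35 monomials).  The same basis is
used by the synthetic encoder (to inject a known offset) and by the
preprocessing fit (to remove it), always on coordinates normalised to
``[-1, 1]`` per axis for numerical conditioning.
"""

from __future__ import annotations

import itertools

import numpy as np

ORDER = 4
N_TERMS = 35  # number of monomials x^i y^j z^k with i+j+k <= 4


def monomial_exponents(order: int = ORDER) -> np.ndarray:
    """Exponent triples ``(i, j, k)`` with ``i + j + k <= order``, in a fixed order."""
    exps = [
        (i, j, k)
        for i, j, k in itertools.product(range(order + 1), repeat=3)
        if i + j + k <= order
    ]
    return np.array(sorted(exps, key=lambda e: (sum(e), e)), dtype=int)


def normalized_coords(shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel-centre coordinates of a grid mapped to ``[-1, 1]`` per axis.

    Returns an array of shape ``(nx*ny*nz, 3)`` in C (raster) order.
    """
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=-1)


def design_matrix(coords: np.ndarray, order: int = ORDER) -> np.ndarray:
    """Vandermonde-style matrix of all monomials up to total degree ``order``.

    ``coords`` is ``(n, 3)``; the result is ``(n, n_terms)``.
    """
    coords = np.asarray(coords, dtype=float)
    exps = monomial_exponents(order)
    # powers per axis computed once, then combined
    pows = [np.power.outer(coords[:, ax], np.arange(order + 1)) for ax in range(3)]
    return pows[0][:, exps[:, 0]] * pows[1][:, exps[:, 1]] * pows[2][:, exps[:, 2]]


def evaluate(coeffs: np.ndarray, coords: np.ndarray, order: int = ORDER) -> np.ndarray:
    """Evaluate a polynomial with coefficient vector ``coeffs`` at ``coords``."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[-1] != len(monomial_exponents(order)):
        raise ValueError(
            f"expected {len(monomial_exponents(order))} coefficients for order {order}, "
            f"got {coeffs.shape[-1]}"
        )
    return design_matrix(coords, order) @ coeffs
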