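"""Independent reference computations used to cross-check the package.

The transfer-matrix routine here follows the 2x2 characteristic-matrix
formulation (Born & Wolf): each layer contributes

    M_j = [[cos δ_j,        i sin δ_j / n_j],
           [i n_j sin δ_j,  cos δ_j       ]],   δ_j = 2π n_j d_j / λ,

the product over layers (top to bottom) acts on (1, n_s), and

    r = (n_0 B − C) / (n_0 B + C),   (B, C)ᵀ = M · (1, n_s)ᵀ.

This is algebraically distinct from the interface-by-interface Abeles
recursion implemented in the package, so agreement is a genuine
cross-check rather than a restatement.
"""

from __future__ import annotations

import numpy as np


def transfer_matrix_reflectance(
    ambient_index: float,
    films: list[tuple[float, float]],
    substrate_index: float,
    wavelength: float,
) -> float:
    """Normal-incidence intensity reflectance of a film stack at one λ.

    ``films`` is a list of (refractive index, thickness_nm) pairs, top first.
    """
    m = np.eye(2, dtype=complex)
    for n, d in films:
        delta = 2.0 * np.pi * n * d / wavelength
        layer = np.array(
            [
                [np.cos(delta), 1j * np.sin(delta) / n],
                [1j * n * np.sin(delta), np.cos(delta)],
            ]
        )
        m = m @ layer
    b, c = m @ np.array([1.0, substrate_index], dtype=complex)
    r = (ambient_index * b - c) / (ambient_index * b + c)
    return float(np.abs(r) ** 2)


def single_film_airy_reflectance(
    n0: float, n1: float, ns: float, d: float, wavelength: float
) -> float:
    """Airy summation for a single film — closed form independent of both
    the recursion and the matrix method."""
    r01 = (n0 - n1) / (n0 + n1)
    r1s = (n1 - ns) / (n1 + ns)
    phase = np.exp(-2j * (2.0 * np.pi * n1 * d / wavelength))
    r = (r01 + r1s * phase) / (1 + r01 * r1s * phase)
    return float(np.abs(r) ** 2)


def langmuir_thickness(
    k_on: float, k_off: float, conc: float, d_max: float, t: np.ndarray
) -> np.ndarray:
    """Closed-form 1:1 Langmuir association curve."""
    k_obs = k_on * conc + k_off
    if k_obs == 0:
        return np.zeros_like(np.asarray(t, dtype=float))
    d_eq = d_max * k_on * conc / k_obs
    return d_eq * (1.0 - np.exp(-k_obs * np.asarray(t, dtype=float)))
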