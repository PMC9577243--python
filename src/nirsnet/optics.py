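"""Modified Beer-Lambert optics shared by the simulator and preprocessing.

The modified Beer-Lambert law relates optical-density change to chromophore
concentration change:

    dOD(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR] * d * DPF

with molar extinction coefficients ``eps`` (1/cm per mol/L), source-detector
distance ``d`` (cm) and the unitless differential pathlength factor DPF.
Concentrations are carried in micromol/L throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EXTINCTION_UM", "extinction_matrix", "DEFAULT_WAVELENGTHS", "DEFAULT_DPF"]

DEFAULT_WAVELENGTHS = (760.0, 850.0)
DEFAULT_DPF = 6.0

# Molar extinction coefficients, 1/cm per mol/L, {wavelength: (HbO, HbR)}.
EXTINCTION_UM: dict[float, tuple[float, float]] = {
    690.0: (276.0, 2051.96),
    760.0: (586.0, 1548.52),
    780.0: (710.0, 1075.44),
    808.0: (844.0, 751.84),
    830.0: (974.0, 693.04),
    850.0: (1058.0, 691.32),
}


def extinction_matrix(
    wavelengths: tuple[float, float],
    table: dict[float, tuple[float, float]] | None = None,
) -> np.ndarray:
    """2x2 extinction matrix E with E[i] = (eps_HbO, eps_HbR) at wavelength i.

    Raises if a wavelength is missing from the table or if the resulting
    matrix is singular (the two wavelengths must discriminate HbO from HbR).
    """
    table = EXTINCTION_UM if table is None else table
    rows = []
    for wl in wavelengths:
        if wl not in table:
            raise KeyError(
                f"no extinction coefficients for {wl} nm; available: "
                f"{sorted(table)}"
            )
        rows.append(table[wl])
    e = np.asarray(rows, dtype=float)
    if abs(np.linalg.det(e)) < 1e-12 * np.abs(e).max() ** 2:
        raise ValueError(
            f"extinction matrix for wavelengths {wavelengths} is singular; "
            "chromophores cannot be separated"
        )
    return e
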