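"""Independent optics oracles used by the FLIC tests.

Recursive Airy (Fresnel + geometric-series) thin-film reflection and explicit
direct+reflected field superposition; deliberately shares no code with the
package's characteristic-matrix implementation.
"""

import numpy as np

from fusionscope.flic_optics import FlicOpticsParams


def fresnel(n1: complex, n2: complex) -> complex:
    return (n1 - n2) / (n1 + n2)


def airy_reflection(params: FlicOpticsParams, lam: float, d_ox: float) -> complex:
    """Top-down recursion r = (r01 + r' e^{2i delta}) / (1 + r01 r' e^{2i delta})."""
    layers = [
        (complex(params.n_membrane), params.membrane_nm),
        (complex(params.n_water), params.water_cleft_nm),
        (complex(params.n_oxide), d_ox),
    ]
    indices = [complex(params.n_water)] + [n for n, _ in layers] + [
        complex(params.n_silicon)
    ]
    r = fresnel(indices[-2], indices[-1])
    for i in range(len(layers) - 1, -1, -1):
        n, d = layers[i]
        phase = np.exp(2j * 2 * np.pi * n * d / lam)
        r01 = fresnel(indices[i], n)
        r = (r01 + r * phase) / (1 + r01 * r * phase)
    return complex(r)


def field_superposition_intensity(
    params: FlicOpticsParams, d_ox: float, h: float
) -> float:
    """Probed intensity |direct + silicon-reflected wave|^2, per light pass."""
    out = 1.0
    for lam in (params.excitation_wavelength, params.emission_wavelength):
        r = airy_reflection(params, lam, d_ox)
        k = 2 * np.pi * params.n_water / lam
        out *= abs(1.0 + r * np.exp(2j * k * h)) ** 2
    return out
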