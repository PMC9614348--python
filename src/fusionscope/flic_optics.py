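"""Fluorescence interference contrast (FLIC) optics: forward model and inversion.

A fluorophore held at height ``h`` above a membrane that rests on a patterned
silicon chip sits in the standing wave formed by interference of the direct
and silicon-reflected light, for both excitation and emission.  The chip
carries 16 microfabricated silicon-oxide terraces of different thickness, so
each terrace samples the standing wave at a different phase; a set of 16
terrace intensities therefore encodes the axial dye position, which is
recovered by fitting the five-layer optical model
(bulk Si / variable SiO2 / 4 nm water / 4 nm membrane / bulk water).

The model here is the normal-incidence scalar version: the sub-stack below the
dye plane is reduced to one complex reflection coefficient per wavelength by
the standard characteristic-matrix (transfer-matrix) recursion, and the probed
intensity is the product of the excitation and emission standing-wave factors

    F(d_ox, h) = |1 + r_ex e^{2 i k_ex h}|^2 * |1 + r_em e^{2 i k_em h}|^2

with k = 2 pi n_water / lambda.  Angular integration over the objective
aperture is deliberately not modelled; the forward model is isolated behind
``flic_intensity`` so a full angular model could replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .stats import AnovaResult, one_way_anova_vs_control

__all__ = [
    "OpticalLayer",
    "FlicOpticsParams",
    "FlicMeasurement",
    "FlicFitResult",
    "default_oxide_thicknesses",
    "stack_reflection",
    "flic_intensity",
    "fit_dye_height",
    "distance_change_report",
]


@dataclass(frozen=True)
class OpticalLayer:
    """One layer of the interference stack.

    ``thickness`` is in nm and absent (None) for the two semi-infinite bulk
    media.  The refractive index may be complex; silicon absorbs weakly in the
    visible so Im(n) > 0.
    """

    name: str
    refractive_index: complex
    thickness: float | None = None

    def __post_init__(self) -> None:
        if self.thickness is not None and self.thickness < 0:
            raise ValueError("thickness must be >= 0")
        if np.imag(self.refractive_index) < 0:
            raise ValueError("Im(n) must be >= 0 (absorbing convention)")


@dataclass(frozen=True)
class FlicOpticsParams:
    """Five-layer stack (bottom-up) and the excitation/emission wavelengths.

    Defaults describe Alexa546 on the standard chip: n_Si = 4.086 + 0.028i,
    n_SiO2 = 1.46, n_water = 1.33, n_membrane = 1.45, lambda_ex = 546 nm,
    lambda_em = 590 nm (under a 610/60 band-pass).  The 4 nm water cleft and
    4 nm membrane are held constant; only the oxide thickness varies between
    terraces.
    """

    n_silicon: complex = 4.086 + 0.028j
    n_oxide: float = 1.46
    n_water: float = 1.33
    n_membrane: float = 1.45
    water_cleft_nm: float = 4.0
    membrane_nm: float = 4.0
    excitation_wavelength: float = 546.0
    emission_wavelength: float = 590.0

    def __post_init__(self) -> None:
        if self.excitation_wavelength <= 0 or self.emission_wavelength <= 0:
            raise ValueError("wavelengths must be positive")
        if self.water_cleft_nm < 0 or self.membrane_nm < 0:
            raise ValueError("layer thicknesses must be >= 0")

    def stack(self, oxide_thickness: float) -> list[OpticalLayer]:
        """Ordered layers bottom-up for a given oxide terrace thickness."""
        return [
            OpticalLayer("silicon", self.n_silicon, None),
            OpticalLayer("oxide", self.n_oxide, oxide_thickness),
            OpticalLayer("water_cleft", self.n_water, self.water_cleft_nm),
            OpticalLayer("membrane", self.n_membrane, self.membrane_nm),
            OpticalLayer("water", self.n_water, None),
        ]


def default_oxide_thicknesses() -> np.ndarray:
    """Default 16 terrace oxide thicknesses (nm): 4 blocks of 4, ~10-300 nm."""
    return np.round(np.linspace(10.0, 300.0, 16), 1)


@dataclass
class FlicMeasurement:
    """One set of 16 (oxide thickness, intensity) pairs from one chip image."""

    oxide_thicknesses: np.ndarray
    intensities: np.ndarray
    set_id: int = 0

    def __post_init__(self) -> None:
        self.oxide_thicknesses = np.asarray(self.oxide_thicknesses, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.oxide_thicknesses.shape != (16,) or self.intensities.shape != (16,):
            raise ValueError("a FLIC measurement holds exactly 16 terrace pairs")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class FlicFitResult:
    """Fitted dye height (nm above the membrane surface) with nuisance params."""

    dye_height: float
    scale: float
    background: float
    rss: float
    set_id: int = 0


def stack_reflection(
    params: FlicOpticsParams, wavelength: float, oxide_thickness: float
) -> complex:
    """Complex reflection coefficient of the sub-stack below the dye plane.

    Normal incidence, referenced at the top membrane surface, for light coming
    from bulk water: membrane (4 nm) / water cleft (4 nm) / oxide (variable) /
    bulk silicon, by the characteristic-matrix recursion.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    n_in = complex(params.n_water)
    n_sub = complex(params.n_silicon)
    # finite layers from the incidence side downwards
    layers = [
        (complex(params.n_membrane), params.membrane_nm),
        (complex(params.n_water), params.water_cleft_nm),
        (complex(params.n_oxide), float(oxide_thickness)),
    ]
    # sign convention: fields go as e^{i(kz - wt)} with Im(n) >= 0 absorbing,
    # matching the +2ikh round-trip phase used in flic_intensity
    m = np.eye(2, dtype=complex)
    for n, d in layers:
        delta = 2.0 * np.pi * n * d / wavelength
        layer_m = np.array(
            [
                [np.cos(delta), -1j * np.sin(delta) / n],
                [-1j * n * np.sin(delta), np.cos(delta)],
            ],
            dtype=complex,
        )
        m = m @ layer_m
    num = n_in * (m[0, 0] + m[0, 1] * n_sub) - (m[1, 0] + m[1, 1] * n_sub)
    den = n_in * (m[0, 0] + m[0, 1] * n_sub) + (m[1, 0] + m[1, 1] * n_sub)
    return complex(num / den)


def flic_intensity(
    params: FlicOpticsParams,
    oxide_thickness: "float | np.ndarray",
    dye_height: "float | np.ndarray",
) -> "float | np.ndarray":
    """Relative detected intensity of a dye at ``dye_height`` nm over the membrane.

    Product of the excitation and emission standing-wave factors; broadcasts
    over arrays of oxide thickness and height.
    """
    d_ox = np.atleast_1d(np.asarray(oxide_thickness, dtype=float))
    h = np.asarray(dye_height, dtype=float)
    if np.any(h < 0):
        raise ValueError("dye_height must be >= 0")
    out = np.ones(np.broadcast_shapes(d_ox.shape, h.shape))
    for lam in (params.excitation_wavelength, params.emission_wavelength):
        r = np.array([stack_reflection(params, lam, d) for d in d_ox])
        k = 2.0 * np.pi * params.n_water / lam
        field_factor = np.abs(1.0 + r * np.exp(2j * k * h)) ** 2
        out = out * field_factor
    if np.isscalar(oxide_thickness) and np.isscalar(dye_height):
        return float(out[0])
    return out


def _forward_matrix(
    params: FlicOpticsParams, oxide_thicknesses: np.ndarray, heights: np.ndarray
) -> np.ndarray:
    """F[i, j] = flic_intensity(terrace i, height j), vectorised over heights."""
    d_ox = np.asarray(oxide_thicknesses, dtype=float)
    h = np.asarray(heights, dtype=float)
    out = np.ones((d_ox.size, h.size))
    for lam in (params.excitation_wavelength, params.emission_wavelength):
        r = np.array([stack_reflection(params, lam, d) for d in d_ox])
        k = 2.0 * np.pi * params.n_water / lam
        out *= np.abs(1.0 + r[:, None] * np.exp(2j * k * h[None, :])) ** 2
    return out


def _linear_fit(f: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-height least squares of y ~ scale*f + background; returns scale, bg, rss."""
    n = f.shape[0]
    sf = f.sum(axis=0)
    sff = (f * f).sum(axis=0)
    sy = y.sum()
    sfy = f.T @ y
    det = n * sff - sf * sf
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    scale = (n * sfy - sf * sy) / det
    bg = (sy - scale * sf) / n
    resid = y[:, None] - scale[None, :] * f - bg[None, :]
    rss = (resid * resid).sum(axis=0)
    return scale, bg, rss


def fit_dye_height(
    meas: FlicMeasurement,
    params: FlicOpticsParams | None = None,
    search: tuple[float, float] = (0.0, 40.0),
    grid_step: float = 0.05,
) -> FlicFitResult:
    """Invert one 16-terrace intensity set for the dye height.

    Minimises sum_i (I_i - scale*F(d_ox_i, h) - background)^2 by a grid search
    over ``h`` in ``search`` (nm) — the amplitude and background are profiled
    out by linear least squares at each grid point — followed by local
    refinement of ``h`` with bounded scalar minimisation.  The search interval
    must stay within one unambiguous interference period.

    Raises
    ------
    ValueError
        If the 16 intensities are all (numerically) equal, which carries no
        height information.
    """
    if params is None:
        params = FlicOpticsParams()
    y = meas.intensities
    if np.ptp(y) <= 1e-12 * max(1.0, np.abs(y).max()):
        raise ValueError("uninformative measurement: all 16 intensities equal")
    lo, hi = float(search[0]), float(search[1])
    if not (0.0 <= lo < hi):
        raise ValueError("invalid search interval")

    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    f = _forward_matrix(params, meas.oxide_thicknesses, grid)
    scale, bg, rss = _linear_fit(f, y)
    best = int(np.nanargmin(rss))

    def objective(h: float) -> float:
        fh = _forward_matrix(params, meas.oxide_thicknesses, np.array([h]))
        _, _, r = _linear_fit(fh, y)
        return float(r[0])

    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, grid.size - 1)]
    if a < b:
        res = minimize_scalar(objective, bounds=(a, b), method="bounded")
        h_hat = float(res.x)
    else:
        h_hat = float(grid[best])
    fh = _forward_matrix(params, meas.oxide_thicknesses, np.array([h_hat]))
    s, c, r = _linear_fit(fh, y)
    return FlicFitResult(h_hat, float(s[0]), float(c[0]), float(r[0]), meas.set_id)


def distance_change_report(
    condition_fits: "list[np.ndarray | list[float]]",
    control_fits: "list[np.ndarray | list[float]]",
) -> tuple[pd.DataFrame, float, AnovaResult]:
    """Per-repeat dye-height change vs control, with mean and significance.

    Parameters are paired lists: element ``i`` of each holds the fitted
    heights (nm) of repeat ``i`` under the alcohol condition and its matched
    control.  Returns (per-repeat table, mean delta, ANOVA of the per-repeat
    condition/control means).
    """
    if len(condition_fits) != len(control_fits) or not condition_fits:
        raise ValueError("condition and control repeats must be paired and non-empty")
    cond_means = np.array([np.mean(np.asarray(c, float)) for c in condition_fits])
    ctrl_means = np.array([np.mean(np.asarray(c, float)) for c in control_fits])
    deltas = cond_means - ctrl_means
    table = pd.DataFrame(
        {
            "repeat": np.arange(len(deltas)),
            "mean_height_condition_nm": cond_means,
            "mean_height_control_nm": ctrl_means,
            "delta_nm": deltas,
        }
    )
    anova = one_way_anova_vs_control(
        {"control": ctrl_means, "condition": cond_means}, control="control"
    )
    return table, float(deltas.mean()), anova
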