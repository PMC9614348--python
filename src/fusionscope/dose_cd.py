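"""Alcohol dose unit conversions and CD secondary-structure aggregation.

Doses in the fusion experiments are prepared volumetrically (% v/v) but
pharmacology is discussed in molar units, so the package carries exact
conversions between % v/v, mM and % w/v for a given alcohol.  Circular
dichroism deconvolution (performed externally, e.g. by BeStSel) yields eight
secondary-structure fractions; downstream reporting groups them into Helix,
Beta and Other/Turn and expresses conditions as deltas against the no-alcohol
control.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AlcoholSpec",
    "ETHANOL",
    "METHANOL",
    "CdComposition",
    "CdAggregate",
    "vv_to_molar",
    "molar_to_vv",
    "molar_to_wv",
    "vv_to_wv",
    "aggregate_cd",
]


@dataclass(frozen=True)
class AlcoholSpec:
    """Physical constants of an alcohol used for dose conversions.

    Parameters
    ----------
    name : str
        Alcohol name.
    molecular_weight : float
        Molar mass in g/mol.
    density : float
        Density of the pure alcohol in g/mL (25 degC by default).
    """

    name: str
    molecular_weight: float
    density: float

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0 or self.density <= 0:
            raise ValueError("molecular_weight and density must be positive")


#: Densities at 25 degC.
ETHANOL = AlcoholSpec("ethanol", molecular_weight=46.07, density=0.785)
METHANOL = AlcoholSpec("methanol", molecular_weight=32.04, density=0.792)


def _check_nonneg(x: float, name: str) -> None:
    if x < 0:
        raise ValueError(f"{name} must be non-negative, got {x}")


def vv_to_molar(percent_vv: float, spec: AlcoholSpec = ETHANOL) -> float:
    """Convert % v/v (mL alcohol per 100 mL solution) to mM.

    mM = (percent_vv / 100) * density[g/mL] * 1000[mL/L] / MW[g/mol] * 1000
    """
    _check_nonneg(percent_vv, "percent_vv")
    return percent_vv / 100.0 * spec.density * 1000.0 / spec.molecular_weight * 1000.0


def molar_to_vv(mM: float, spec: AlcoholSpec = ETHANOL) -> float:
    """Convert mM to % v/v; exact inverse of :func:`vv_to_molar`."""
    _check_nonneg(mM, "mM")
    return mM * spec.molecular_weight / (spec.density * 1000.0 * 1000.0) * 100.0


def molar_to_wv(mM: float, spec: AlcoholSpec = ETHANOL) -> float:
    """Convert mM to % w/v (g alcohol per 100 mL solution)."""
    _check_nonneg(mM, "mM")
    # g per 100 mL = mol/L * g/mol / 10
    return mM / 1000.0 * spec.molecular_weight / 10.0


def vv_to_wv(percent_vv: float, spec: AlcoholSpec = ETHANOL) -> float:
    """Convert % v/v to % w/v (g per 100 mL)."""
    _check_nonneg(percent_vv, "percent_vv")
    return percent_vv * spec.density


_HELIX = ("Helix1", "Helix2")
_BETA = ("Anti1", "Anti2", "Anti3", "Para")
_OTHER = ("Turn", "Others")
CD_CATEGORIES = _HELIX + _BETA + _OTHER


@dataclass(frozen=True)
class CdComposition:
    """Eight-category secondary-structure fractions from CD deconvolution."""

    Helix1: float
    Helix2: float
    Anti1: float
    Anti2: float
    Anti3: float
    Para: float
    Turn: float
    Others: float

    def __post_init__(self) -> None:
        total = 0.0
        for name in CD_CATEGORIES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction {name}={v} outside [0, 1]")
            total += v
        if total > 1.0 + 1e-6:
            raise ValueError(f"fractions sum to {total} > 1")

    @classmethod
    def from_dict(cls, d: dict) -> "CdComposition":
        missing = [k for k in CD_CATEGORIES if k not in d]
        if missing:
            raise ValueError(f"missing CD categories: {missing}")
        return cls(**{k: float(d[k]) for k in CD_CATEGORIES})


@dataclass(frozen=True)
class CdAggregate:
    """Grouped secondary-structure content, optionally as delta vs control."""

    helix: float
    beta: float
    other_turn: float
    delta_helix: float | None = None
    delta_beta: float | None = None
    delta_other_turn: float | None = None


def _group(c: CdComposition) -> tuple[float, float, float]:
    helix = sum(getattr(c, k) for k in _HELIX)
    beta = sum(getattr(c, k) for k in _BETA)
    other = sum(getattr(c, k) for k in _OTHER)
    return helix, beta, other


def aggregate_cd(c: CdComposition, control: CdComposition | None = None) -> CdAggregate:
    """Group the eight CD fractions into Helix, Beta and Other/Turn.

    Helix = Helix1 + Helix2; Beta = Anti1 + Anti2 + Anti3 + Para;
    Other/Turn = Turn + Others.  When ``control`` is given, the per-category
    deltas (sample minus control) are attached, which is how structural change
    relative to the 0% alcohol sample is reported.
    """
    h, b, o = _group(c)
    if control is None:
        return CdAggregate(h, b, o)
    hc, bc, oc = _group(control)
    return CdAggregate(h, b, o, h - hc, b - bc, o - oc)
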