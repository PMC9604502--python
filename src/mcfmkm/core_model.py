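"""Microdosimetric kinetic model core: survival terms, overkill correction, RBE.

Clonogenic survival follows the linear-quadratic model
S(D) = exp(−αD − βD²). For an ion exposure characterized by a lineal-energy
dose distribution d(y), the exposure-specific terms are dose-mean values of
the per-event biological effect over the spectrum:

    α = Σᵢ (α0 + β0·z_d(yᵢ)) · c(yᵢ) · wᵢ
    β = β0 · [Σᵢ c(yᵢ) · wᵢ]²

where z_d(y) = K·y/(ρπr_d²) is the specific energy imparted per event to a
subnuclear domain of radius r_d, α0 and β0 are the LQM terms in the y → 0
limit, and wᵢ = d(yᵢ)·dyᵢ is the per-bin dose-probability mass. The
saturation (overkill) correction

    c(y) = (1 − e^{−u}) / u,
    u(y) = (α0 + β0·z_d(y)) · z_n(y) + β0 · z_n(y)²

with z_n evaluated for the whole nucleus of radius R_n, accounts for the
non-Poisson statistics of lethal lesions when a single traversal deposits a
large dose: c → 1 at low y and decays like 1/u at high y, producing the
characteristic rise-then-fall of RBE with LET.

The α integrand is evaluated in the expanded form (α0 + β0·z_d)·c so that it
stays defined at α0 = 0, where the factored textbook form α0·(1 + (β0/α0)z_d)
would divide by zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np

from .exceptions import DegenerateSpectrumError
from .spectra import MicrodosimetricSpectrum, normalize

if TYPE_CHECKING:  # pragma: no cover
    from .cell_params import CellLineParams

__all__ = [
    "KEV_UM_TO_GY",
    "LQMTerms",
    "PredictionRecord",
    "specific_energy_per_event",
    "correction_factor",
    "alpha_mkm",
    "beta_mkm",
    "survival",
    "dose_for_survival",
    "rbe",
    "predict",
    "DEFAULT_SURVIVAL_LEVELS",
]

#: Unit-closure constant for z = K·y/(ρπr²): with y in keV/µm, r in µm and ρ
#: in g/cm³, 1 keV/µm/µm² per g/cm³ = 1.602e-16 J / 1e-15 kg ≈ 0.16022 Gy.
KEV_UM_TO_GY = 0.16022

#: Survival levels reported by default: 50%, 10% and 1%.
DEFAULT_SURVIVAL_LEVELS = (0.5, 0.1, 0.01)

_SERIES_U_CUTOFF = 1e-8


@dataclass(frozen=True)
class LQMTerms:
    """A linear-quadratic pair: alpha in Gy⁻¹, beta in Gy⁻²."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not np.isfinite(self.alpha) or not np.isfinite(self.beta):
            raise ValueError("LQM terms must be finite")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("LQM terms must be non-negative")


@dataclass(frozen=True)
class PredictionRecord:
    """One spectrum's predicted LQM terms and RBE values.

    ``rbe`` maps surviving fraction (e.g. 0.1) to RBE at that level.
    """

    label: str
    y_d: float
    alpha: float
    beta: float
    rbe: Mapping[float, float]
    let: float | None = field(default=None)


def specific_energy_per_event(
    y: float | np.ndarray, r: float, rho: float = 1.0
) -> float | np.ndarray:
    """Mean specific energy (Gy) a single event of lineal energy ``y`` (keV/µm)
    imparts to a spherical site of radius ``r`` (µm) and density ``rho`` (g/cm³):
    z = K·y/(ρπr²)."""
    if r <= 0:
        raise ValueError("site radius must be positive")
    if rho <= 0:
        raise ValueError("density must be positive")
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("lineal energy must be non-negative")
    z = KEV_UM_TO_GY * y / (rho * np.pi * r**2)
    return float(z) if z.ndim == 0 else z


def _saturation_u(y: np.ndarray, params: "CellLineParams") -> np.ndarray:
    z_d = specific_energy_per_event(y, params.rd, params.rho)
    z_n = specific_energy_per_event(y, params.rn, params.rho)
    return (params.alpha0 + params.beta0 * z_d) * z_n + params.beta0 * z_n**2


def correction_factor(
    y: float | np.ndarray, params: "CellLineParams"
) -> float | np.ndarray:
    """Non-Poisson overkill correction c(y) = (1 − e^{−u})/u, in (0, 1].

    Evaluated via expm1 for stability; for u below 1e-8 the series
    1 − u/2 + u²/6 is used to avoid cancellation. c(0) = 1 and c is strictly
    decreasing in y.
    """
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    u = _saturation_u(y_arr, params)
    c = np.empty_like(u)
    small = u < _SERIES_U_CUTOFF
    c[small] = 1.0 - u[small] / 2.0 + u[small] ** 2 / 6.0
    with np.errstate(over="ignore"):
        c[~small] = -np.expm1(-u[~small]) / u[~small]
    return float(c[0]) if np.isscalar(y) or np.asarray(y).ndim == 0 else c


def _require_normalized(spectrum: MicrodosimetricSpectrum) -> MicrodosimetricSpectrum:
    if spectrum.total <= 0:
        raise DegenerateSpectrumError("spectrum carries no mass")
    return normalize(spectrum)


def alpha_mkm(spectrum: MicrodosimetricSpectrum, params: "CellLineParams") -> float:
    """Linear LQM term: dose-mean of (α0 + β0·z_d(y))·c(y) over the spectrum."""
    s = _require_normalized(spectrum)
    y = s.representative_y
    z_d = specific_energy_per_event(y, params.rd, params.rho)
    c = correction_factor(y, params)
    return float(np.dot((params.alpha0 + params.beta0 * z_d) * c, s.weights))


def beta_mkm(spectrum: MicrodosimetricSpectrum, params: "CellLineParams") -> float:
    """Quadratic LQM term: β0 times the squared dose-mean of c(y); ≤ β0."""
    s = _require_normalized(spectrum)
    c = correction_factor(s.representative_y, params)
    return float(params.beta0 * np.dot(c, s.weights) ** 2)


def survival(dose: float, terms: LQMTerms) -> float:
    """Surviving fraction S = exp(−αD − βD²) at absorbed dose D (Gy)."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    return float(np.exp(-terms.alpha * dose - terms.beta * dose**2))


def dose_for_survival(terms: LQMTerms, s: float) -> float:
    """Dose (Gy) at which the LQM curve reaches surviving fraction ``s``.

    Uses the rationalized root D = −2·ln s / (α + sqrt(α² − 4β·ln s)), which
    remains well defined at β = 0.
    """
    if not 0 < s < 1:
        raise ValueError("surviving fraction must lie in (0, 1)")
    if terms.alpha == 0 and terms.beta == 0:
        raise ValueError("no finite dose: alpha and beta are both zero")
    log_s = np.log(s)
    return float(
        -2.0 * log_s / (terms.alpha + np.sqrt(terms.alpha**2 - 4.0 * terms.beta * log_s))
    )


def rbe(terms: LQMTerms, ref_terms: LQMTerms, s: float) -> float:
    """RBE at surviving fraction ``s``: ratio of the reference-photon dose to
    the test-radiation dose giving the same survival,

        RBE_S = [α + sqrt(α² − 4β·ln S)] / [α_ref + sqrt(α_ref² − 4β_ref·ln S)].
    """
    if not 0 < s < 1:
        raise ValueError("surviving fraction must lie in (0, 1)")
    for t in (terms, ref_terms):
        if t.alpha == 0 and t.beta == 0:
            raise ValueError("degenerate LQM terms (alpha = beta = 0)")
    log_s = np.log(s)
    num = terms.alpha + np.sqrt(terms.alpha**2 - 4.0 * terms.beta * log_s)
    den = ref_terms.alpha + np.sqrt(ref_terms.alpha**2 - 4.0 * ref_terms.beta * log_s)
    return float(num / den)


def predict(
    spectrum: MicrodosimetricSpectrum,
    params: "CellLineParams",
    s_levels: Iterable[float] = DEFAULT_SURVIVAL_LEVELS,
    label: str | None = None,
    let: float | None = None,
) -> PredictionRecord:
    """Predict α, β and RBE at the requested survival levels for one spectrum."""
    s_norm = _require_normalized(spectrum)
    terms = LQMTerms(alpha_mkm(s_norm, params), beta_mkm(s_norm, params))
    ref = LQMTerms(params.alpha_ref, params.beta_ref)
    rbe_map = {float(s): rbe(terms, ref, float(s)) for s in s_levels}
    return PredictionRecord(
        label=label or s_norm.label or "spectrum",
        y_d=s_norm.dose_mean_lineal_energy(),
        alpha=terms.alpha,
        beta=terms.beta,
        rbe=rbe_map,
        let=let,
    )
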