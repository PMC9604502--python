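"""A-priori derivation of cell-line model parameters.

All parameters of the survival model — nucleus radius R_n, domain radius
r_d, photon-reference LQM terms and their y → 0 limits — are derived from
species constants, karyotype/morphology and photon dose-response alone; no
ion-exposure survival data enter at any point.

The chain is:

1. Mean DNA content of the asynchronized population, Γ = γ·p·ξ, with γ the
   haploid DNA content of the species, p the ploidy (x/x_n for aneuploid
   lines with mean chromosome count x) and ξ a cell-cycle factor (4/3 for
   asynchronized populations, reflecting the mixture of G1/S/G2 DNA states).
2. Nucleus radius R_n from, in order of preference: a measured radius of the
   trypsinized (spherical) nucleus; the cross-sectional area of attached
   nuclei (sphere or volume-matched oblate-spheroid reading); or a
   phenomenological linear correlation with Γ.
3. Domain radius r_d = R_n·(λ/Γ)^(1/3): the radius of the average nuclear
   subvolume holding λ = 2 Mbp of DNA, the size of a giant chromatin loop,
   assuming DNA uniformly fills the nucleus.
4. Photon terms α_ref, β_ref, optionally as entry-count-weighted means over
   several reference exposures; then β0 = β_ref and
   α0 = α_ref − β0·z_d(ȳ_D,ref), with ȳ_D,ref the dose-mean lineal energy
   of the reference photons (2.3 keV/µm for γ-rays and MV X-rays,
   4.3 keV/µm for ~200 kV X-rays).

A negative α0 means the photon parameter set is internally inconsistent
(β0·z_d exceeds α_ref) and raises :class:`InconsistentParametersError`.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core_model import specific_energy_per_event
from .exceptions import ConfigError, InconsistentParametersError, UnknownSpeciesError

__all__ = [
    "round_half_up",
    "SpeciesConstants",
    "SPECIES_CONSTANTS",
    "KaryotypeInfo",
    "PhotonReference",
    "CellLineParams",
    "ploidy",
    "mean_dna_content",
    "nucleus_radius_from_area_sphere",
    "nucleus_radius_from_area_spheroid",
    "nucleus_radius_from_dna",
    "domain_radius",
    "weighted_reference_lqm",
    "alpha0",
    "build_cell_line",
    "load_cell_line_library",
    "ExtrapolationWarning",
]

logger = logging.getLogger(__name__)

#: Default cell-cycle factor for asynchronized populations.
DEFAULT_XI = 4.0 / 3.0

#: DNA content of one giant chromatin loop, the assumed domain size (Mbp).
DEFAULT_LAMBDA_MBP = 2.0

#: Default dose-mean lineal energy of the reference photons (keV/µm).
DEFAULT_YD_REF = 2.3

#: Calibration window of the DNA→R_n correlation (Mbp). Outside it the
#: correlation is an extrapolation and a warning is emitted.
DNA_RADIUS_WINDOW_MBP = (5000.0, 17000.0)


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (the convention of printed parameter
    tables), unlike Python's banker's rounding."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class ExtrapolationWarning(UserWarning):
    """The DNA-content→nucleus-radius correlation is used outside its
    calibrated range."""


@dataclass(frozen=True)
class SpeciesConstants:
    """Haploid DNA content (Mbp) and normal chromosome set count."""

    gamma_mbp: float
    x_n: int


SPECIES_CONSTANTS: dict[str, SpeciesConstants] = {
    "human": SpeciesConstants(3050.0, 23),
    "rat": SpeciesConstants(2750.0, 21),
    "chinese_hamster": SpeciesConstants(2700.0, 11),
    "mouse": SpeciesConstants(2650.0, 20),
}


def get_species(name: str) -> SpeciesConstants:
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    try:
        return SPECIES_CONSTANTS[key]
    except KeyError:
        known = ", ".join(sorted(SPECIES_CONSTANTS))
        raise UnknownSpeciesError(f"unknown species {name!r}; known: {known}") from None


@dataclass(frozen=True)
class KaryotypeInfo:
    """Ploidy description: exactly one of mean chromosome number ``x`` or
    ploidy ``p`` (a ``pseudodiploid`` flag in configs maps to p = 2)."""

    species: str
    x: float | None = None
    p: float | None = None
    xi: float = DEFAULT_XI

    def __post_init__(self):
        if (self.x is None) == (self.p is None):
            raise ConfigError("provide exactly one of mean chromosome number x or ploidy p")
        if self.x is not None and self.x <= 0:
            raise ConfigError("mean chromosome number must be positive")
        if self.p is not None and self.p <= 0:
            raise ConfigError("ploidy must be positive")
        if self.xi <= 0:
            raise ConfigError("cell-cycle factor xi must be positive")

    def resolve_ploidy(self) -> float:
        if self.p is not None:
            return float(self.p)
        return ploidy(self.x, self.species)


@dataclass(frozen=True)
class PhotonReference:
    """One photon dose-response set with its number of associated ion entries."""

    alpha: float
    beta: float
    n: int = 1

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigError("photon reference alpha and beta must be positive")
        if self.n < 1:
            raise ConfigError("entry count n must be >= 1")


@dataclass(frozen=True)
class CellLineParams:
    """Complete cell-line parameter set for the survival model.

    ``provenance`` records, per derived field, how it was obtained.
    """

    name: str
    rn: float  # nucleus radius, µm
    rd: float  # domain radius, µm
    alpha_ref: float  # Gy⁻¹
    beta_ref: float  # Gy⁻²
    alpha0: float  # Gy⁻¹
    beta0: float  # Gy⁻²
    rho: float = 1.0  # g/cm³
    gamma_mbp: float | None = field(default=None, compare=False)
    yd_ref: float = field(default=DEFAULT_YD_REF, compare=False)
    provenance: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not 0 < self.rd < self.rn:
            raise ConfigError(
                f"require 0 < rd < Rn, got rd={self.rd:g}, Rn={self.rn:g}"
            )
        if self.alpha0 < 0:
            raise InconsistentParametersError(
                f"alpha0 = {self.alpha0:g} Gy^-1 is negative"
            )
        if self.beta0 != self.beta_ref:
            raise ConfigError("beta0 must equal beta_ref")
        if self.rho <= 0:
            raise ConfigError("density must be positive")


def ploidy(x: float, species: str) -> float:
    """Approximate ploidy of an aneuploid population: p = x / x_n(species)."""
    if x <= 0:
        raise ValueError("mean chromosome number must be positive")
    return float(x) / get_species(species).x_n


def mean_dna_content(species: str, p: float, xi: float = DEFAULT_XI) -> float:
    """Mean DNA content of the irradiated population, Γ = γ·p·ξ (Mbp)."""
    if p <= 0 or xi <= 0:
        raise ValueError("ploidy and cell-cycle factor must be positive")
    return get_species(species).gamma_mbp * p * xi


def nucleus_radius_from_area_sphere(area_um2: float) -> float:
    """R_n = sqrt(A/π): sphere whose great circle equals the measured
    cross-sectional area of the attached nucleus."""
    if area_um2 <= 0:
        raise ValueError("cross-sectional area must be positive")
    return float(np.sqrt(area_um2 / np.pi))


def nucleus_radius_from_area_spheroid(area_um2: float) -> float:
    """Radius of the sphere matching the volume of an oblate spheroid with
    equatorial radius sqrt(A/π) and minor semi-axis a third of it:
    R_n = sqrt(A/π)·3^(−1/3). Attached nuclei are flattened, so this reading
    is always smaller than the plain spherical one."""
    return nucleus_radius_from_area_sphere(area_um2) * 3.0 ** (-1.0 / 3.0)


def nucleus_radius_from_dna(gamma_mbp: float) -> float:
    """Phenomenological correlation R_n = 3.5 µm + 0.144 µm/Gbp · Γ.

    Calibrated on morphological data for asynchronized lines; outside
    roughly 5–17 Gbp it is an extrapolation and an
    :class:`ExtrapolationWarning` is emitted.
    """
    if gamma_mbp <= 0:
        raise ValueError("DNA content must be positive")
    lo, hi = DNA_RADIUS_WINDOW_MBP
    if not lo <= gamma_mbp <= hi:
        warnings.warn(
            f"DNA content {gamma_mbp:g} Mbp outside the calibrated window "
            f"[{lo:g}, {hi:g}] Mbp of the radius correlation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return 3.5 + 0.144 * (gamma_mbp / 1000.0)


def domain_radius(
    rn: float, gamma_mbp: float, lam_mbp: float = DEFAULT_LAMBDA_MBP
) -> float:
    """Domain radius r_d = R_n·(λ/Γ)^(1/3) (µm): the average subvolume of the
    nucleus containing one chromatin loop's worth (λ) of DNA."""
    if rn <= 0:
        raise ValueError("nucleus radius must be positive")
    if lam_mbp <= 0:
        raise ValueError("domain DNA content must be positive")
    if gamma_mbp < lam_mbp:
        raise ValueError(
            f"DNA content {gamma_mbp:g} Mbp below the domain content {lam_mbp:g} Mbp"
        )
    return rn * (lam_mbp / gamma_mbp) ** (1.0 / 3.0)


def weighted_reference_lqm(
    sets: Sequence[PhotonReference],
) -> tuple[float, float]:
    """Entry-count-weighted mean photon terms:
    α_ref = Σ α_i·n_i / Σ n_i and likewise for β_ref. Weighting by the number
    of ion entries keeps sparsely used photon experiments from biasing the
    average."""
    if not sets:
        raise ValueError("need at least one photon reference set")
    n = np.array([s.n for s in sets], dtype=float)
    a = np.array([s.alpha for s in sets])
    b = np.array([s.beta for s in sets])
    return float(np.dot(a, n) / n.sum()), float(np.dot(b, n) / n.sum())


def alpha0(
    alpha_ref: float,
    beta0: float,
    yd_ref: float,
    rd: float,
    rho: float = 1.0,
) -> float:
    """y → 0 limit of the linear term: α0 = α_ref − β0·z_d(ȳ_D,ref).

    The photon reference is treated as a quasi-delta exposure at its
    dose-mean lineal energy (its saturation correction is ≈ 1), so the
    measured α_ref already contains the intra-domain quadratic contribution
    β0·z_d, which is subtracted off.
    """
    if yd_ref < 0:
        raise ValueError("reference dose-mean lineal energy must be >= 0")
    z_d = specific_energy_per_event(yd_ref, rd, rho)
    a0 = alpha_ref - beta0 * z_d
    if a0 < 0:
        raise InconsistentParametersError(
            f"alpha0 = {alpha_ref:g} - {beta0:g}*{z_d:.4g} = {a0:.4g} Gy^-1 < 0: "
            "the photon parameter set is inconsistent (beta0*z_d exceeds "
            "alpha_ref); check beta_ref, the domain radius, or yD_ref"
        )
    return float(a0)


# --- configuration ----------------------------------------------------------

_NUCLEUS_KEYS = {"radius_um", "area_um2", "from_dna"}
_KNOWN_KEYS = {
    "name",
    "species",
    "karyotype",
    "xi",
    "nucleus",
    "photon_reference",
    "yD_ref_keV_um",
    "rho_g_cm3",
    "notes",
    "printed_values",
}


def _parse_karyotype(cfg: Mapping, species: str, xi: float) -> KaryotypeInfo:
    kcfg = cfg.get("karyotype")
    if not isinstance(kcfg, Mapping):
        raise ConfigError("config must provide a karyotype mapping")
    flags = [k for k in ("x", "p", "pseudodiploid") if k in kcfg]
    if len(flags) != 1:
        raise ConfigError(
            "karyotype must carry exactly one of x, p or pseudodiploid"
        )
    if "pseudodiploid" in kcfg:
        if not kcfg["pseudodiploid"]:
            raise ConfigError("pseudodiploid flag must be true when present")
        return KaryotypeInfo(species=species, p=2.0, xi=xi)
    if "p" in kcfg:
        return KaryotypeInfo(species=species, p=float(kcfg["p"]), xi=xi)
    return KaryotypeInfo(species=species, x=float(kcfg["x"]), xi=xi)


def build_cell_line(config: Mapping | str | os.PathLike) -> CellLineParams:
    """Derive a full :class:`CellLineParams` from a configuration.

    ``config`` is a mapping (or path to a YAML file holding one) with keys
    ``species``, ``karyotype`` ({x | p | pseudodiploid}), optional ``xi``,
    ``nucleus`` (exactly one of ``radius_um``, ``area_um2`` (+ ``method``:
    "sphere"|"spheroid"), or ``from_dna``), ``photon_reference`` (list of
    {alpha, beta, n}) and optional ``yD_ref_keV_um``. The provenance of every
    derived quantity is recorded on the result and logged.
    """
    if not isinstance(config, Mapping):
        with open(config, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"{config} does not hold a configuration mapping")
        config = loaded

    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    for key in ("species", "karyotype", "nucleus", "photon_reference"):
        if key not in config:
            raise ConfigError(f"missing required configuration key {key!r}")

    name = str(config.get("name", "cell line"))
    species = str(config["species"])
    get_species(species)  # fail early on unknown species
    xi = float(config.get("xi", DEFAULT_XI))
    rho = float(config.get("rho_g_cm3", 1.0))
    yd_ref = float(config.get("yD_ref_keV_um", DEFAULT_YD_REF))
    provenance: dict[str, str] = {}

    karyotype = _parse_karyotype(config, species, xi)
    p = karyotype.resolve_ploidy()
    provenance["p"] = (
        f"given ploidy p={p:g}"
        if karyotype.p is not None
        else f"x/x_n = {karyotype.x:g}/{get_species(species).x_n}"
    )
    gamma = mean_dna_content(species, p, xi)
    provenance["gamma"] = f"gamma({species})*p*xi = {gamma:.1f} Mbp"

    ncfg = config["nucleus"]
    if not isinstance(ncfg, Mapping):
        raise ConfigError("nucleus must be a mapping")
    sources = [k for k in _NUCLEUS_KEYS if ncfg.get(k) not in (None, False)]
    if len(sources) != 1:
        raise ConfigError(
            "nucleus must specify exactly one of radius_um, area_um2 or from_dna; "
            f"got {sources or 'none'}"
        )
    source = sources[0]
    if source == "radius_um":
        rn = float(ncfg["radius_um"])
        if rn <= 0:
            raise ConfigError("measured nucleus radius must be positive")
        provenance["rn"] = "measured radius of the trypsinized nucleus"
    elif source == "area_um2":
        method = ncfg.get("method", "sphere")
        if method == "sphere":
            rn = nucleus_radius_from_area_sphere(float(ncfg["area_um2"]))
        elif method == "spheroid":
            rn = nucleus_radius_from_area_spheroid(float(ncfg["area_um2"]))
        else:
            raise ConfigError(f"unknown nucleus area method {method!r}")
        provenance["rn"] = f"cross-sectional area, {method} reading"
    else:
        rn = nucleus_radius_from_dna(gamma)
        provenance["rn"] = "DNA-content correlation Rn = 3.5 + 0.144*Gamma[Gbp]"

    rd = domain_radius(rn, gamma)
    provenance["rd"] = "rd = Rn*(lambda/Gamma)^(1/3), lambda = 2 Mbp"

    refs_cfg = config["photon_reference"]
    if not isinstance(refs_cfg, Sequence) or not refs_cfg:
        raise ConfigError("photon_reference must be a non-empty list")
    refs = [
        PhotonReference(float(r["alpha"]), float(r["beta"]), int(r.get("n", 1)))
        for r in refs_cfg
    ]
    alpha_ref, beta_ref = weighted_reference_lqm(refs)
    provenance["alpha_ref"] = provenance["beta_ref"] = (
        f"entry-count-weighted mean over {len(refs)} photon set(s)"
        if len(refs) > 1
        else "single photon reference set"
    )

    beta0 = beta_ref
    provenance["beta0"] = "beta0 = beta_ref (photon saturation correction ~ 1)"
    a0 = alpha0(alpha_ref, beta0, yd_ref, rd, rho)
    provenance["alpha0"] = (
        f"alpha0 = alpha_ref - beta0*z_d(yD_ref = {yd_ref:g} keV/um)"
    )

    params = CellLineParams(
        name=name,
        rn=rn,
        rd=rd,
        alpha_ref=alpha_ref,
        beta_ref=beta_ref,
        alpha0=a0,
        beta0=beta0,
        rho=rho,
        gamma_mbp=gamma,
        yd_ref=yd_ref,
        provenance=provenance,
    )
    for fieldname, how in provenance.items():
        logger.info("%s: %s <- %s", name, fieldname, how)
    return params


def load_cell_line_library() -> dict[str, dict]:
    """Bundled configurations for the 14 benchmark cell lines."""
    from importlib.resources import files

    text = files("mcfmkm.data").joinpath("cell_lines.yaml").read_text(encoding="utf-8")
    library = yaml.safe_load(text)
    for name, cfg in library.items():
        cfg.setdefault("name", name)
    return library
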