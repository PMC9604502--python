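"""Lineal-energy dose-probability distributions.

The radiation-quality input of the microdosimetric kinetic model is the
dose probability density d(y) of the lineal energy y (keV/µm): the fraction
of absorbed dose delivered by single events with lineal energy near y.
Spectra are stored as per-bin probability *mass* d(y)·dy on a canonical
logarithmic grid, which turns every model integral into a plain weighted
sum and makes files independent of the binning convention.

Besides file I/O, the module provides idealized generators used in place of
full Monte Carlo radiation transport:

* a delta spectrum (all dose at one lineal energy) — the photon reference
  exposures are modelled this way via their representative dose-mean value;
* a track-segment spectrum for a sphere crossed by straight ion tracks
  under µ-randomness, whose chord-length distribution gives
  d(y) = 3·y²/y_max³ with y_max = (3/2)·LET, hence the closed-form moments
  ȳF = LET and ȳD = (9/8)·LET;
* a log-normal frequency spectrum with closed-form dose-mean
  exp(µ + 3σ²/2), convenient as an analytic fixture.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DegenerateSpectrumError, GridRangeError, SpectrumParseError

__all__ = [
    "LinealEnergyGrid",
    "MicrodosimetricSpectrum",
    "normalize",
    "dose_mean_lineal_energy",
    "frequency_mean_lineal_energy",
    "from_frequency_distribution",
    "generate_delta",
    "generate_track_segment",
    "generate_lognormal",
    "read_spectrum",
    "write_spectrum",
]

#: default grid span and resolution (keV/µm, bins per decade)
DEFAULT_Y_MIN = 1e-2
DEFAULT_Y_MAX = 1e7
DEFAULT_BINS_PER_DECADE = 50

_LOG_UNIFORM_RTOL = 1e-12
_NORMALIZATION_ATOL = 1e-10


@dataclass(frozen=True)
class LinealEnergyGrid:
    """Strictly increasing, logarithmically uniform bin edges in keV/µm.

    The representative lineal energy of each bin is the geometric mean of
    its edges, the unbiased centre for log-uniform binning.
    """

    edges: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("grid needs at least two bin edges")
        if not np.all(np.isfinite(edges)) or edges[0] <= 0:
            raise ValueError("bin edges must be finite and positive")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        ratios = edges[1:] / edges[:-1]
        mean_ratio = np.exp(np.mean(np.log(ratios)))
        if np.max(np.abs(ratios / mean_ratio - 1.0)) > _LOG_UNIFORM_RTOL:
            raise ValueError("bin edges are not logarithmically uniform")

    @classmethod
    def log_uniform(
        cls,
        y_min: float = DEFAULT_Y_MIN,
        y_max: float = DEFAULT_Y_MAX,
        bins_per_decade: int = DEFAULT_BINS_PER_DECADE,
    ) -> "LinealEnergyGrid":
        """Build a log-uniform grid covering [y_min, y_max]."""
        if y_min <= 0 or y_max <= y_min:
            raise ValueError("require 0 < y_min < y_max")
        n_bins = int(round(np.log10(y_max / y_min) * bins_per_decade))
        if n_bins < 1:
            raise ValueError("grid span too small for the requested resolution")
        edges = 10.0 ** np.linspace(np.log10(y_min), np.log10(y_max), n_bins + 1)
        return cls(edges)

    @classmethod
    def default(cls) -> "LinealEnergyGrid":
        """The canonical scoring grid: 1e-2 to 1e7 keV/µm, 50 bins/decade."""
        return cls.log_uniform()

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def representative(self) -> np.ndarray:
        """Per-bin representative lineal energy: geometric mean of the edges."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def span(self) -> tuple[float, float]:
        return float(self.edges[0]), float(self.edges[-1])

    def locate(self, y: float) -> int:
        """Index of the bin containing lineal energy ``y``.

        Bins are half-open [lo, hi); the last bin is closed at the top edge.
        """
        lo, hi = self.span
        if not (lo <= y <= hi):
            raise GridRangeError(
                f"lineal energy {y:g} keV/µm outside grid span [{lo:g}, {hi:g}]"
            )
        if y == hi:
            return self.n_bins - 1
        return int(np.searchsorted(self.edges, y, side="right")) - 1

    def refined(self, factor: int = 2) -> "LinealEnergyGrid":
        """Same span with ``factor`` times more bins (for convergence checks)."""
        lo, hi = self.span
        n_bins = self.n_bins * factor
        edges = 10.0 ** np.linspace(np.log10(lo), np.log10(hi), n_bins + 1)
        return LinealEnergyGrid(edges)


@dataclass(frozen=True)
class MicrodosimetricSpectrum:
    """Binned dose-probability distribution of the lineal energy.

    ``weights[i]`` is the probability mass d(y)·dy carried by bin i of
    ``grid``; ``representative_y[i]`` is the lineal energy attributed to it.
    """

    grid: LinealEnergyGrid
    weights: np.ndarray
    label: str | None = field(default=None, compare=False)

    def __post_init__(self):
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", weights)
        if weights.shape != (self.grid.n_bins,):
            raise ValueError(
                f"expected {self.grid.n_bins} weights, got shape {weights.shape}"
            )
        if not np.all(np.isfinite(weights)):
            raise ValueError("weights must be finite")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        if not np.any(weights > 0):
            raise DegenerateSpectrumError("spectrum carries no positive mass")

    @property
    def representative_y(self) -> np.ndarray:
        return self.grid.representative

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    @property
    def is_normalized(self) -> bool:
        return abs(self.total - 1.0) <= _NORMALIZATION_ATOL

    def normalize(self) -> "MicrodosimetricSpectrum":
        return normalize(self)

    def dose_mean_lineal_energy(self) -> float:
        return dose_mean_lineal_energy(self)

    def frequency_mean_lineal_energy(self) -> float:
        return frequency_mean_lineal_energy(self)


def normalize(spectrum: MicrodosimetricSpectrum) -> MicrodosimetricSpectrum:
    """Scale the weights to unit total mass, preserving their shape."""
    total = spectrum.total
    if total <= 0:  # unreachable through the constructor, kept as a guard
        raise DegenerateSpectrumError("cannot normalize zero total mass")
    return MicrodosimetricSpectrum(
        spectrum.grid, spectrum.weights / total, label=spectrum.label
    )


def dose_mean_lineal_energy(spectrum: MicrodosimetricSpectrum) -> float:
    """Dose-mean lineal energy ȳD = Σ yᵢ·wᵢ over the normalized spectrum."""
    s = normalize(spectrum)
    return float(np.dot(s.representative_y, s.weights))


def frequency_mean_lineal_energy(spectrum: MicrodosimetricSpectrum) -> float:
    """Frequency-mean lineal energy ȳF = [Σ wᵢ/yᵢ]⁻¹.

    Under the dose weighting the event frequency in a bin is proportional to
    w/y, so the frequency mean is the dose-weighted harmonic mean of y.
    """
    s = normalize(spectrum)
    y = s.representative_y
    if np.any(y[s.weights > 0] <= 0):
        raise ValueError("frequency mean undefined for support at y <= 0")
    return float(1.0 / np.dot(s.weights, 1.0 / y))


def from_frequency_distribution(
    f_weights: np.ndarray, grid: LinealEnergyGrid, label: str | None = None
) -> MicrodosimetricSpectrum:
    """Convert per-bin event-frequency mass f(y)·dy into dose weighting.

    The dose delivered by events in a bin scales with the lineal energy,
    d(y) ∝ y·f(y), so dose weights are yᵢ·fᵢ renormalized.
    """
    f = np.asarray(f_weights, dtype=float)
    if f.shape != (grid.n_bins,):
        raise ValueError("frequency weights do not match the grid")
    if np.any(~np.isfinite(f)) or np.any(f < 0):
        raise ValueError("frequency weights must be finite and non-negative")
    d = grid.representative * f
    if not np.any(d > 0):
        raise DegenerateSpectrumError("frequency distribution carries no mass")
    return normalize(MicrodosimetricSpectrum(grid, d, label=label))


def generate_delta(
    y_star: float, grid: LinealEnergyGrid | None = None
) -> MicrodosimetricSpectrum:
    """All dose in the single bin containing ``y_star`` (keV/µm)."""
    grid = grid or LinealEnergyGrid.default()
    idx = grid.locate(y_star)
    weights = np.zeros(grid.n_bins)
    weights[idx] = 1.0
    return MicrodosimetricSpectrum(grid, weights, label=f"delta_y{y_star:g}")


def generate_track_segment(
    let: float, grid: LinealEnergyGrid | None = None
) -> MicrodosimetricSpectrum:
    """Idealized single-ion spectrum for a spherical site under µ-randomness.

    A straight track of constant LET crossing a sphere deposits y = LET·l/l̄
    along a chord of length l, with mean chord l̄. The triangular chord-length
    density gives the dose density d(y) = 3y²/y_max³ on [0, y_max] with
    y_max = (3/2)·LET; each bin receives the exact integral of d(y) over the
    bin intersected with the support. Closed-form moments: ȳF = LET,
    ȳD = (9/8)·LET. Delta rays, straggling and track curvature are ignored.
    """
    if not np.isfinite(let) or let <= 0:
        raise ValueError("LET must be positive")
    grid = grid or LinealEnergyGrid.default()
    y_max = 1.5 * let
    lo = np.clip(grid.edges[:-1], 0.0, y_max)
    hi = np.clip(grid.edges[1:], 0.0, y_max)
    weights = (hi**3 - lo**3) / y_max**3
    if not np.any(weights > 0):
        raise DegenerateSpectrumError(
            f"track-segment support [0, {y_max:g}] keV/µm lies below the grid floor"
        )
    return normalize(MicrodosimetricSpectrum(grid, weights, label=f"track_LET{let:g}"))


def generate_lognormal(
    mu: float, sigma: float, grid: LinealEnergyGrid | None = None
) -> MicrodosimetricSpectrum:
    """Log-normal event-frequency spectrum converted to dose weighting.

    ``mu`` and ``sigma`` are the mean and standard deviation of ln y for the
    *frequency* distribution f(y); the resulting dose distribution is then
    log-normal with median shifted by σ², so ȳD = exp(µ + 3σ²/2).
    """
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError("sigma must be positive")
    grid = grid or LinealEnergyGrid.default()
    f = np.diff(stats.lognorm.cdf(grid.edges, s=sigma, scale=np.exp(mu)))
    if not np.any(f > 0):
        raise DegenerateSpectrumError("log-normal mass falls outside the grid span")
    return from_frequency_distribution(f, grid, label=f"lognormal_mu{mu:g}_s{sigma:g}")


# --- file I/O ---------------------------------------------------------------
#
# Spectrum files are two-column delimited text: lineal energy (keV/µm) and
# dose-probability mass per bin. Comma, tab or whitespace delimited; lines
# starting with '#' are comments; one optional non-numeric header line is
# tolerated. Written files use comma with a '# y[keV/um], d(y)dy' header.


def _split_line(line: str) -> list[str]:
    if "," in line:
        return [tok.strip() for tok in line.split(",")]
    if "\t" in line:
        return [tok.strip() for tok in line.split("\t")]
    return line.split()


def read_spectrum(
    path: str | os.PathLike | io.TextIOBase,
    grid: LinealEnergyGrid | None = None,
) -> MicrodosimetricSpectrum:
    """Read a two-column spectrum file and snap it onto ``grid``.

    Arbitrary y values are assigned, mass-conservingly, to the grid bin
    containing them; the result is normalized. Raises
    :class:`SpectrumParseError` (naming the line) on malformed input.
    """
    grid = grid or LinealEnergyGrid.default()
    if isinstance(path, io.TextIOBase):
        lines = path.readlines()
        name = getattr(path, "name", "<stream>")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
        name = os.fspath(path)

    ys: list[float] = []
    ws: list[float] = []
    weights = np.zeros(grid.n_bins)
    seen_header = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = _split_line(line)
        if len(tokens) < 2:
            raise SpectrumParseError(f"expected two columns, got {line!r}", lineno)
        try:
            y, w = float(tokens[0]), float(tokens[1])
        except ValueError:
            if not ys and not seen_header:  # tolerate one header line
                seen_header = True
                continue
            raise SpectrumParseError(f"non-numeric row {line!r}", lineno) from None
        if not np.isfinite(y) or not np.isfinite(w):
            raise SpectrumParseError(f"non-finite value in row {line!r}", lineno)
        if w < 0:
            raise SpectrumParseError(f"negative weight {w:g}", lineno)
        if ys and y <= ys[-1]:
            raise SpectrumParseError(
                f"lineal energies not strictly increasing at y={y:g}", lineno
            )
        try:
            idx = grid.locate(y)
        except GridRangeError as exc:
            raise SpectrumParseError(str(exc), lineno) from None
        ys.append(y)
        ws.append(w)
        weights[idx] += w

    if not ys:
        raise SpectrumParseError(f"no data rows found in {name}")
    if not np.any(weights > 0):
        raise DegenerateSpectrumError(f"spectrum in {name} carries zero total mass")
    return normalize(
        MicrodosimetricSpectrum(grid, weights, label=os.path.basename(str(name)))
    )


def write_spectrum(
    spectrum: MicrodosimetricSpectrum, path: str | os.PathLike | io.TextIOBase
) -> None:
    """Write the non-empty bins as comma-separated (y, mass) rows."""
    s = normalize(spectrum)
    rows = ["# y[keV/um], d(y)dy"]
    for y, w in zip(s.representative_y, s.weights):
        if w > 0:
            rows.append(f"{y:.12g},{w:.12g}")
    text = "\n".join(rows) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
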