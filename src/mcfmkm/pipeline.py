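"""Batch orchestration: RBE tables, survival-entry filtering, fixtures.

This module strings the spectrum and model layers together for the common
workflows: predicting α/β/RBE for a batch of spectra and writing the result
as CSV; screening tabulated in-vitro survival entries with the standard
exclusion rules (spread-out Bragg peaks, very low energies, synchronized
populations, unusable linear-quadratic sets); and generating a
self-contained, fully deterministic fixture suite on disk.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import core_model, spectra
from .cell_params import CellLineParams, load_cell_line_library
from .core_model import DEFAULT_SURVIVAL_LEVELS, PredictionRecord
from .exceptions import MCFMKMError
from .spectra import MicrodosimetricSpectrum

__all__ = [
    "rbe_table",
    "records_to_frame",
    "write_rbe_table",
    "LQMSet",
    "SurvivalEntry",
    "filter_survival_entries",
    "read_survival_entries",
    "write_survival_entries",
    "generate_fixture_suite",
    "FIXTURE_LET_SWEEP",
]

logger = logging.getLogger(__name__)

#: LET values (keV/µm) of the track-segment sweep in the fixture suite.
FIXTURE_LET_SWEEP = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0)


# --- RBE tables -------------------------------------------------------------


def rbe_table(
    spectra_in: Sequence[MicrodosimetricSpectrum],
    params: CellLineParams,
    s_levels: Iterable[float] = DEFAULT_SURVIVAL_LEVELS,
    labels: Sequence[str] | None = None,
    lets: Sequence[float | None] | None = None,
) -> list[PredictionRecord]:
    """Predict one :class:`PredictionRecord` per spectrum, order preserved.

    A failure in any spectrum aborts the whole table with the spectrum's
    label named in the error.
    """
    if not spectra_in:
        raise ValueError("need at least one spectrum")
    s_levels = tuple(s_levels)
    records = []
    for i, spec in enumerate(spectra_in):
        label = labels[i] if labels is not None else (spec.label or f"spectrum_{i}")
        let = lets[i] if lets is not None else None
        try:
            records.append(
                core_model.predict(spec, params, s_levels, label=label, let=let)
            )
        except (MCFMKMError, ValueError) as exc:
            raise MCFMKMError(f"prediction failed for spectrum {label!r}: {exc}") from exc
    return records


def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Tabulate records with stable column order:
    label, LET_keV_um, yD_keV_um, alpha_Gy-1, beta_Gy-2, rbe_S<level>..."""
    levels: list[float] = []
    for rec in records:
        for s in rec.rbe:
            if s not in levels:
                levels.append(s)
    rows = []
    for rec in records:
        row = {
            "label": rec.label,
            "LET_keV_um": rec.let if rec.let is not None else np.nan,
            "yD_keV_um": rec.y_d,
            "alpha_Gy-1": rec.alpha,
            "beta_Gy-2": rec.beta,
        }
        for s in levels:
            row[f"rbe_S{s:g}"] = rec.rbe.get(s, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_rbe_table(
    records: Sequence[PredictionRecord], path: str | os.PathLike
) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.10g")


# --- survival-entry filtering ----------------------------------------------


@dataclass(frozen=True)
class LQMSet:
    """One fitted linear-quadratic set for an entry (fields may be missing)."""

    alpha: float | None = None
    beta: float | None = None
    alpha_ref: float | None = None
    beta_ref: float | None = None


@dataclass(frozen=True)
class SurvivalEntry:
    """One tabulated ion-exposure survival experiment.

    ``lqm_sets`` typically holds two sets: the original publication's fit and
    a database re-fit. Any field of either set may be absent.
    """

    ion: str
    energy_mev_n: float | None
    let_kev_um: float | None
    beam_type: str | None  # "monoenergetic" | "SOBP"
    synchronized: bool | None
    lqm_sets: tuple[LQMSet, ...] = field(default_factory=tuple)


#: Rejection reason codes, in the order the rules are applied.
REASON_MALFORMED = "malformed"
REASON_SOBP = "sobp_beam"
REASON_LOW_ENERGY = "energy_below_1_mev_n"
REASON_SYNCHRONIZED = "synchronized_population"
REASON_NO_PHOTON_REFERENCE = "no_positive_photon_reference"
REASON_NEGATIVE_BETA = "no_nonnegative_beta"
REASON_ALPHA_ZERO_LARGE_BETA = "alpha_zero_large_beta"


def _rejection_reason(entry: SurvivalEntry, beta_large_threshold: float) -> str | None:
    if (
        entry.beam_type is None
        or entry.energy_mev_n is None
        or entry.synchronized is None
    ):
        return REASON_MALFORMED
    if str(entry.beam_type).strip().lower() in {"sobp", "spread-out", "spread_out"}:
        return REASON_SOBP
    if entry.energy_mev_n < 1.0:
        return REASON_LOW_ENERGY
    if entry.synchronized:
        return REASON_SYNCHRONIZED
    sets = entry.lqm_sets
    if not any(
        s.alpha_ref is not None
        and s.beta_ref is not None
        and s.alpha_ref > 0
        and s.beta_ref > 0
        for s in sets
    ):
        return REASON_NO_PHOTON_REFERENCE
    if not any(s.beta is not None and s.beta >= 0 for s in sets):
        return REASON_NEGATIVE_BETA
    ion_sets = [s for s in sets if s.alpha is not None and s.beta is not None]
    if len(ion_sets) == 1:
        only = ion_sets[0]
        if only.alpha == 0 and only.beta > beta_large_threshold:
            return REASON_ALPHA_ZERO_LARGE_BETA
    return None


def filter_survival_entries(
    entries: Sequence[SurvivalEntry],
    beta_large_threshold: float = 0.0,
) -> tuple[list[SurvivalEntry], list[tuple[SurvivalEntry, str]]]:
    """Screen entries for model benchmarking; return (kept, rejected).

    Rules, applied in order, each with its reason code: malformed records
    (missing beam type, energy, or synchronization flag); spread-out
    Bragg-peak exposures; ion energy below 1 MeV/n; synchronized
    populations; no linear-quadratic set with positive photon reference
    terms; no set with a non-negative ion β; and entries whose only ion set
    lists α = 0 with β above ``beta_large_threshold`` (default 0, i.e. any
    positive β), a fingerprint of a degenerate fit.
    """
    kept: list[SurvivalEntry] = []
    rejected: list[tuple[SurvivalEntry, str]] = []
    for entry in entries:
        reason = _rejection_reason(entry, beta_large_threshold)
        if reason is None:
            kept.append(entry)
        else:
            rejected.append((entry, reason))
    return kept, rejected


_ENTRY_COLUMNS = [
    "ion",
    "energy_MeV_n",
    "LET_keV_um",
    "beam_type",
    "synchronized",
    "alpha_orig",
    "beta_orig",
    "alpha_ref_orig",
    "beta_ref_orig",
    "alpha_refit",
    "beta_refit",
    "alpha_ref_refit",
    "beta_ref_refit",
]


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_survival_entries(path: str | os.PathLike) -> list[SurvivalEntry]:
    """Read survival entries from the package's CSV convention (columns as in
    :data:`_ENTRY_COLUMNS`; empty cells mean missing)."""
    df = pd.read_csv(path)
    entries = []
    for _, row in df.iterrows():
        sync = row.get("synchronized")
        if isinstance(sync, str):
            sync = sync.strip().lower() in {"true", "yes", "1"}
        elif sync is not None and not (isinstance(sync, float) and np.isnan(sync)):
            sync = bool(sync)
        else:
            sync = None
        beam = row.get("beam_type")
        if isinstance(beam, float) and np.isnan(beam):
            beam = None
        entries.append(
            SurvivalEntry(
                ion=str(row.get("ion", "")),
                energy_mev_n=_opt(row.get("energy_MeV_n")),
                let_kev_um=_opt(row.get("LET_keV_um")),
                beam_type=beam,
                synchronized=sync,
                lqm_sets=(
                    LQMSet(
                        _opt(row.get("alpha_orig")),
                        _opt(row.get("beta_orig")),
                        _opt(row.get("alpha_ref_orig")),
                        _opt(row.get("beta_ref_orig")),
                    ),
                    LQMSet(
                        _opt(row.get("alpha_refit")),
                        _opt(row.get("beta_refit")),
                        _opt(row.get("alpha_ref_refit")),
                        _opt(row.get("beta_ref_refit")),
                    ),
                ),
            )
        )
    return entries


def write_survival_entries(
    entries: Sequence[SurvivalEntry], path: str | os.PathLike
) -> None:
    rows = []
    for e in entries:
        s1 = e.lqm_sets[0] if len(e.lqm_sets) > 0 else LQMSet()
        s2 = e.lqm_sets[1] if len(e.lqm_sets) > 1 else LQMSet()
        rows.append(
            [
                e.ion,
                e.energy_mev_n,
                e.let_kev_um,
                e.beam_type,
                e.synchronized,
                s1.alpha,
                s1.beta,
                s1.alpha_ref,
                s1.beta_ref,
                s2.alpha,
                s2.beta,
                s2.alpha_ref,
                s2.beta_ref,
            ]
        )
    pd.DataFrame(rows, columns=_ENTRY_COLUMNS).to_csv(path, index=False)


# --- fixture suite ----------------------------------------------------------


def _toy_survival_entries() -> list[SurvivalEntry]:
    """Six entries each violating one exclusion rule, plus one keeper."""
    ok = LQMSet(alpha=0.4, beta=0.02, alpha_ref=0.2, beta_ref=0.02)
    return [
        SurvivalEntry("12C", 50.0, 80.0, "SOBP", False, (ok,)),
        SurvivalEntry("12C", 0.5, 500.0, "monoenergetic", False, (ok,)),
        SurvivalEntry("12C", 50.0, 80.0, "monoenergetic", True, (ok,)),
        SurvivalEntry(
            "12C", 50.0, 80.0, "monoenergetic", False,
            (LQMSet(alpha=0.4, beta=0.02, alpha_ref=0.2, beta_ref=0.0),),
        ),
        SurvivalEntry(
            "12C", 50.0, 80.0, "monoenergetic", False,
            (LQMSet(alpha=0.4, beta=-0.01, alpha_ref=0.2, beta_ref=0.02),),
        ),
        SurvivalEntry(
            "12C", 50.0, 80.0, "monoenergetic", False,
            (LQMSet(alpha=0.0, beta=0.3, alpha_ref=0.2, beta_ref=0.02),),
        ),
        SurvivalEntry("12C", 50.0, 80.0, "monoenergetic", False, (ok,)),
    ]


def generate_fixture_suite(out_dir: str | os.PathLike) -> list[str]:
    """Write the deterministic fixture suite; return the manifest.

    Contents: the 14 bundled cell-line configurations, a track-segment LET
    sweep (:data:`FIXTURE_LET_SWEEP`), photon-like delta spectra at 2.3 and
    4.3 keV/µm, and a toy survival-entry table exercising every filter rule.
    Regeneration is byte-identical.
    """
    out = Path(out_dir)
    manifest: list[str] = []

    cells_dir = out / "cell_lines"
    cells_dir.mkdir(parents=True, exist_ok=True)
    library = load_cell_line_library()
    for name, cfg in sorted(library.items()):
        safe = name.replace("/", "_").replace(",", "_").replace(" ", "_")
        path = cells_dir / f"{safe}.yaml"
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({name: cfg}, fh, sort_keys=True)
        manifest.append(str(path.relative_to(out)))

    spec_dir = out / "spectra"
    spec_dir.mkdir(parents=True, exist_ok=True)
    for let in FIXTURE_LET_SWEEP:
        path = spec_dir / f"track_LET{let:g}.csv"
        spectra.write_spectrum(spectra.generate_track_segment(let), path)
        manifest.append(str(path.relative_to(out)))
    for y_ref in (2.3, 4.3):
        path = spec_dir / f"photon_y{y_ref:g}.csv"
        spectra.write_spectrum(spectra.generate_delta(y_ref), path)
        manifest.append(str(path.relative_to(out)))

    entries_path = out / "survival_entries.csv"
    write_survival_entries(_toy_survival_entries(), entries_path)
    manifest.append(str(entries_path.relative_to(out)))

    logger.info("fixture suite: %d files under %s", len(manifest), out)
    return manifest
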