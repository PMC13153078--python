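"""Registry of 20 vegetation indices and feature-table assembly.

Each index is an arithmetic combination of reflectances at named
wavelengths (``R800`` = reflectance at the band nearest 800 nm).  The
registry keeps the printed formula of each index; two entries (OSAVI,
MSR) are implemented exactly as printed by the source formulary even
where that deviates from the more common literature form — the canonical
MSR variant is available via ``compute_index(..., canonical_msr=True)``.

An index whose denominator is exactly zero evaluates to NaN (the
undefined marker); downstream assembly either drops such samples or
mean-imputes, per configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from ricelpn.spectra import GridMismatchError, nearest_band
from ricelpn.synth import ParameterError, Spectrum, band_name


class RegistryError(KeyError):
    """Unknown index acronym."""


def _div(num: float, den: float) -> float:
    """Division with NaN as the undefined marker for zero denominators."""
    if den == 0:
        return math.nan
    return num / den


@dataclass(frozen=True)
class IndexDefinition:
    """One spectral index: acronym, required wavelengths, expression."""

    acronym: str
    name: str
    wavelengths_nm: tuple[float, ...]
    expression: str  # human-readable printed form
    func: Callable[[dict[float, float]], float]


def _defs() -> list[IndexDefinition]:
    d = IndexDefinition
    return [
        d("NDVI", "Normalized difference vegetation index", (800, 670),
          "(R800 - R670)/(R800 + R670)",
          lambda R: _div(R[800] - R[670], R[800] + R[670])),
        d("DCNI", "Double-peak canopy nitrogen index", (720, 700, 670),
          "((R720 - R700)/(R700 - R670))/(R700 - R670 + 0.03)",
          lambda R: _div(_div(R[720] - R[700], R[700] - R[670]), R[700] - R[670] + 0.03)),
        d("MTCI", "MERIS terrestrial chlorophyll index", (750, 710, 680),
          "(R750 - R710)/(R710 - R680)",
          lambda R: _div(R[750] - R[710], R[710] - R[680])),
        d("GNDVI", "Green normalized difference vegetation index", (750, 550),
          "(R750 - R550)/(R750 + R550)",
          lambda R: _div(R[750] - R[550], R[750] + R[550])),
        d("NDRE", "Normalized difference red edge index", (790, 720),
          "(R790 - R720)/(R790 + R720)",
          lambda R: _div(R[790] - R[720], R[790] + R[720])),
        d("SIPI", "Structure intensive pigment index", (800, 445, 680),
          "(R800 - R445)/(R800 - R680)",
          lambda R: _div(R[800] - R[445], R[800] - R[680])),
        d("PRI", "Photochemical reflectance index", (570, 530),
          "(R570 - R530)/(R570 + R530)",
          lambda R: _div(R[570] - R[530], R[570] + R[530])),
        d("SRPI", "Simple ratio pigment index", (430, 680),
          "R430/R680",
          lambda R: _div(R[430], R[680])),
        d("PSSR", "Pigment-specific simple ratio", (800, 500),
          "R800/R500",
          lambda R: _div(R[800], R[500])),
        d("PSRI", "Plant senescence reflectance index", (680, 500, 750),
          "(R680 - R500)/R750",
          lambda R: _div(R[680] - R[500], R[750])),
        d("RARS", "Ratio of reflectance spectra", (760, 500),
          "R760/R500",
          lambda R: _div(R[760], R[500])),
        d("GI", "Greenness index", (554, 677),
          "R554/R677",
          lambda R: _div(R[554], R[677])),
        d("PSND", "Pigment-specific normalized difference", (800, 470),
          "(R800 - R470)/(R800 + R470)",
          lambda R: _div(R[800] - R[470], R[800] + R[470])),
        d("OSAVI", "Optimized soil-adjusted vegetation index", (800, 670),
          "1.16*(R800 - R670)/(R800 + R670 + 0.16)",  # printed form kept verbatim
          lambda R: _div(1.16 * (R[800] - R[670]), R[800] + R[670] + 0.16)),
        d("RENDVI", "Red edge NDVI", (750, 705),
          "(R750 - R705)/(R750 + R705)",
          lambda R: _div(R[750] - R[705], R[750] + R[705])),
        d("SR", "Simple ratio vegetation index", (750, 550),
          "R750/R550",
          lambda R: _div(R[750], R[550])),
        d("PBI", "Plant biochemical index", (810, 560),
          "R810/R560",
          lambda R: _div(R[810], R[560])),
        d("LCI", "Leaf chlorophyll index", (850, 710, 680),
          "(R850 - R710)/(R850 + R680)",
          lambda R: _div(R[850] - R[710], R[850] + R[680])),
        d("NPCI", "Normalized pigment chlorophyll ratio index", (670, 460),
          "(R670 - R460)/(R670 + R460)",
          lambda R: _div(R[670] - R[460], R[670] + R[460])),
        d("MSR", "Modified simple ratio", (800, 760, 670),
          "(R800/R760 - 1)/sqrt(R800/R670 + 1)",  # printed form; canonical uses R670 in the first ratio
          lambda R: _div(_div(R[800], R[760]) - 1.0, math.sqrt(_div(R[800], R[670]) + 1.0))),
    ]


INDEX_REGISTRY: dict[str, IndexDefinition] = {d.acronym: d for d in _defs()}

# canonical MSR variant, selectable per call
_MSR_CANONICAL = IndexDefinition(
    "MSR", "Modified simple ratio (canonical)", (800, 670),
    "(R800/R670 - 1)/sqrt(R800/R670 + 1)",
    lambda R: _div(_div(R[800], R[670]) - 1.0, math.sqrt(_div(R[800], R[670]) + 1.0)),
)

NORMALIZED_DIFFERENCE = ("NDVI", "GNDVI", "NDRE", "PRI", "PSND", "RENDVI", "NPCI")
RATIO_TYPE = ("SRPI", "PSSR", "RARS", "GI", "SR", "PBI")


def compute_index(s: Spectrum, definition: str | IndexDefinition, canonical_msr: bool = False) -> float:
    """Evaluate one index on a spectrum using nearest-band reflectances.

    Returns NaN when any denominator in the printed expression is exactly
    zero.  Unknown acronyms raise RegistryError; wavelengths outside the
    sensor range raise OutOfRangeError (from nearest_band).
    """
    if isinstance(definition, str):
        if definition not in INDEX_REGISTRY:
            raise RegistryError(f"unknown index acronym {definition!r}")
        definition = INDEX_REGISTRY[definition]
    if canonical_msr and definition.acronym == "MSR":
        definition = _MSR_CANONICAL
    resolved = {}
    for wl in definition.wavelengths_nm:
        idx, _ = nearest_band(s, wl)
        resolved[wl] = float(s.reflectance[idx])
    value = definition.func(resolved)
    return float(value)


@dataclass
class FeatureTable:
    """Named feature matrix (raw bands + indices) with optional LPN target.

    ``values`` is samples x features; ``target`` aligns with the row index.
    """

    values: pd.DataFrame
    target: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ParameterError("feature names must be unique")
        if self.target is not None and len(self.target) != len(self.values):
            raise ParameterError("target length must match row count")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def subset_rows(self, ids) -> "FeatureTable":
        t = self.target.loc[ids] if self.target is not None else None
        return FeatureTable(self.values.loc[ids].copy(), t.copy() if t is not None else None)

    def subset_features(self, names: list[str]) -> "FeatureTable":
        t = self.target.copy() if self.target is not None else None
        return FeatureTable(self.values[list(names)].copy(), t)


def build_feature_table(
    spectra: list[Spectrum],
    lpn=None,
    sample_ids=None,
    include_bands: bool = True,
    include_indices: bool = True,
    undefined_policy: str = "drop",
) -> FeatureTable:
    """Assemble the modeling table: raw band columns plus index columns.

    Band columns are named ``B_<center>`` (two decimals); index columns use
    registry acronyms.  ``undefined_policy`` governs NaN index values:
    ``"drop"`` removes the affected samples (warning), ``"impute"``
    substitutes the column mean.
    """
    if undefined_policy not in ("drop", "impute"):
        raise ParameterError(f"unknown undefined_policy {undefined_policy!r}")
    if not spectra:
        raise ParameterError("need at least one spectrum")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != wl.shape or not np.array_equal(s.wavelengths, wl):
            raise GridMismatchError("spectra do not share one wavelength grid")
    if lpn is not None and len(lpn) != len(spectra):
        raise ParameterError("lpn length must match number of spectra")
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(len(spectra))]

    blocks = []
    if include_bands:
        mat = np.vstack([s.reflectance for s in spectra])
        blocks.append(pd.DataFrame(mat, columns=[band_name(w) for w in wl], index=sample_ids))
    if include_indices:
        rows = {
            acro: [compute_index(s, d) for s in spectra]
            for acro, d in INDEX_REGISTRY.items()
        }
        blocks.append(pd.DataFrame(rows, index=sample_ids))
    if not blocks:
        raise ParameterError("at least one of include_bands/include_indices must be set")
    values = pd.concat(blocks, axis=1)
    target = pd.Series(np.asarray(lpn, dtype=float), index=sample_ids, name="lpn") if lpn is not None else None

    bad = values.isna().any(axis=1)
    if bad.any():
        if undefined_policy == "drop":
            warnings.warn(
                f"dropping {int(bad.sum())} sample(s) with undefined index values",
                stacklevel=2,
            )
            values = values.loc[~bad]
            if target is not None:
                target = target.loc[~bad]
        else:
            values = values.fillna(values.mean())
    return FeatureTable(values=values, target=target)


def paper_feature_preset(table: FeatureTable, sensor_wavelengths: np.ndarray) -> list[str]:
    """Resolve the published final variable set onto this band grid.

    The published screening retained bands near 775.6, 444.89, 553.58 and
    639.48 nm plus the PSND, MTCI and DCNI indices (MTCI picked by both
    criteria, deduplicated).  Band wavelengths are mapped to the nearest
    center of the current grid.
    """
    probe = Spectrum(wavelengths=sensor_wavelengths, reflectance=np.zeros_like(sensor_wavelengths))
    names: list[str] = []
    for wl in (775.6, 444.89, 553.58, 639.48):
        _, center = nearest_band(probe, wl)
        names.append(band_name(center))
    names += ["PSND", "MTCI", "DCNI"]
    missing = [n for n in names if n not in table.feature_names]
    if missing:
        raise ParameterError(f"preset features missing from table: {missing}")
    return names
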