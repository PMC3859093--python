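"""Published CARS-PLSR calibration equations as fixed, evaluable models.

The published study reports, for each mixture design, a linear NP%
calibration on a handful of LNIR wavelengths, plus the CARS-selected
wavelength sets for every design/band combination.  These are encoded
verbatim (coefficients stored as decimal strings, so the one-decimal
printed precision is authoritative) and exposed as evaluable
:class:`PrintedLinearModel` fixtures.

They are worked-example fixtures for a specific instrument and sample
set — not claims that rerunning CARS on other (e.g. synthetic) data
reproduces them.  Note the Design C equation lists 2496 and 2502 nm
although the stated LNIR range ends at 2500 nm; both are kept verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .dataset import SpectralDataset

__all__ = ["PrintedLinearModel", "load_printed_model", "load_selected_wavelengths",
           "predict_printed"]

#: Matching tolerance (nm) when looking term wavelengths up in a spectrum.
WAVELENGTH_TOL_NM = 2.0


def _resource() -> dict:
    with resources.files("powdercal.data").joinpath("printed_models.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


@dataclass(frozen=True)
class PrintedLinearModel:
    """A published linear calibration: NP% = intercept + Σ coef·R(λ)."""

    design_id: str
    intercept: float
    terms: tuple[tuple[float, float], ...]
    intercept_str: str = ""
    term_strs: tuple[tuple[str, str], ...] = ()

    @property
    def term_count(self) -> int:
        return len(self.terms)

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(w for w, _ in self.terms)

    def to_json(self) -> str:
        return json.dumps(
            {
                "design_id": self.design_id,
                "intercept": self.intercept_str or repr(self.intercept),
                "terms": [[w, c] for w, c in self.term_strs]
                or [[repr(w), repr(c)] for w, c in self.terms],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PrintedLinearModel":
        doc = json.loads(text)
        return cls(
            design_id=doc["design_id"],
            intercept=float(doc["intercept"]),
            terms=tuple((float(w), float(c)) for w, c in doc["terms"]),
            intercept_str=doc["intercept"],
            term_strs=tuple((w, c) for w, c in doc["terms"]),
        )


def load_printed_model(design_id: str) -> PrintedLinearModel:
    """Load the published LNIR calibration equation for a design."""
    key = design_id.upper()
    models = _resource()["models"]
    if key not in models:
        raise ValueError(f"unknown design {design_id!r}; expected one of {sorted(models)}")
    doc = models[key]
    return PrintedLinearModel(
        design_id=key,
        intercept=float(doc["intercept"]),
        terms=tuple((float(w), float(c)) for w, c in doc["terms"]),
        intercept_str=doc["intercept"],
        term_strs=tuple((w, c) for w, c in doc["terms"]),
    )


def load_selected_wavelengths(design_id: str, band: str) -> tuple[float, ...]:
    """Published CARS-selected wavelengths (nm) for a design and band."""
    sets = _resource()["selected_wavelengths_nm"]
    key = design_id.upper()
    if key not in sets:
        raise ValueError(f"unknown design {design_id!r}")
    bands = sets[key]
    b = band.upper()
    if b not in bands:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(bands)}")
    return tuple(float(w) for w in bands[b])


def predict_printed(
    model: PrintedLinearModel,
    spectrum: dict[float, float] | SpectralDataset | tuple[np.ndarray, np.ndarray],
) -> float | np.ndarray:
    """Evaluate a printed model on a spectrum.

    ``spectrum`` may be a {wavelength_nm: reflectance} mapping, a
    ``(wavelengths, reflectance_row)`` pair, or a :class:`SpectralDataset`
    (evaluated per row).  Every term wavelength must be present within
    2 nm; a missing one raises ``KeyError`` naming it.
    """
    if isinstance(spectrum, SpectralDataset):
        cols = [spectrum.column_index(w, tol=WAVELENGTH_TOL_NM) for w in model.wavelengths]
        coefs = np.array([c for _, c in model.terms])
        return model.intercept + spectrum.reflectance[:, cols] @ coefs

    if isinstance(spectrum, dict):
        pts = {float(k): float(v) for k, v in spectrum.items()}
        keys = np.array(sorted(pts))

        def lookup(w: float) -> float:
            idx = int(np.argmin(np.abs(keys - w)))
            if abs(keys[idx] - w) > WAVELENGTH_TOL_NM:
                raise KeyError(
                    f"spectrum provides no reflectance within "
                    f"{WAVELENGTH_TOL_NM} nm of {w} nm"
                )
            return pts[float(keys[idx])]

        return model.intercept + sum(c * lookup(w) for w, c in model.terms)

    wavelengths, refl = spectrum
    wavelengths = np.asarray(wavelengths, dtype=float)
    refl = np.asarray(refl, dtype=float)
    out = model.intercept
    for w, c in model.terms:
        idx = int(np.argmin(np.abs(wavelengths - w)))
        if abs(wavelengths[idx] - w) > WAVELENGTH_TOL_NM:
            raise KeyError(
                f"spectrum provides no reflectance within {WAVELENGTH_TOL_NM} nm of {w} nm"
            )
        out += c * float(refl[idx])
    return out
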