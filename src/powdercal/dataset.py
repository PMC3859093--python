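"""Wavelength-indexed reflectance datasets and spectral band handling.

The central container is :class:`SpectralDataset`: a reflectance matrix
(samples x wavelengths) paired with the reference composition of each
sample — notoginseng powder (NP), *Sophora flavescens* powder (SFP) and
corn flour (CF) percentages by mass, which must balance to 100.

Three instrument bands are used throughout: the visible range VIS
(360–700 nm, 328 variables), short-wave NIR SNIR (700–1040 nm, 378
variables) and long-wave NIR LNIR (937–2500 nm, 241 variables).  The
700 nm column belongs to VIS, so VIS and SNIR partition the combined
visible/short-wave grid; LNIR comes from a second instrument and may
overlap SNIR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SpectralDataset",
    "BandDefinition",
    "BANDS",
    "subset_band",
    "read_dataset",
    "write_dataset",
    "SpectralIOError",
]

#: Metadata columns of the CSV dialect, in serialized order.
META_COLUMNS = ("design_id", "treatment_id", "np_percent", "sfp_percent", "cf_percent")

#: Mass-balance tolerance (% by mass) when validating compositions.
MASS_BALANCE_TOL = 1e-6


class SpectralIOError(ValueError):
    """Malformed spectral table (non-monotone header, ragged rows, ...)."""


@dataclass
class SpectralDataset:
    """Reflectance spectra with per-sample reference compositions.

    Parameters
    ----------
    wavelengths : ndarray, shape (p,)
        Strictly increasing wavelengths in nm.
    reflectance : ndarray, shape (n, p)
        Unitless reflectance in [0, 1].
    np_percent, sfp_percent, cf_percent : ndarray, shape (n,)
        Mass percentages of notoginseng powder and the two adulterants;
        each row must sum to 100.
    treatment_id : ndarray of int, shape (n,)
    design_id : str
        Mixture design label, one of ``{"A", "B", "C"}``.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    np_percent: np.ndarray
    sfp_percent: np.ndarray
    cf_percent: np.ndarray
    treatment_id: np.ndarray
    design_id: str = "A"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        for name in ("np_percent", "sfp_percent", "cf_percent"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.treatment_id = np.asarray(self.treatment_id, dtype=int)
        self.validate()

    def validate(self) -> None:
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be a 1-D vector")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing with no duplicates")
        n, p = self.reflectance.shape
        if p != self.wavelengths.size:
            raise ValueError(
                f"reflectance has {p} columns but {self.wavelengths.size} wavelengths"
            )
        for name in ("np_percent", "sfp_percent", "cf_percent", "treatment_id"):
            vec = getattr(self, name)
            if vec.shape != (n,):
                raise ValueError(f"{name} has length {vec.size}, expected {n} rows")
        total = self.np_percent + self.sfp_percent + self.cf_percent
        if n and np.max(np.abs(total - 100.0)) > MASS_BALANCE_TOL:
            bad = int(np.argmax(np.abs(total - 100.0)))
            raise ValueError(
                f"mass balance violated: row {bad} sums to {total[bad]!r}, expected 100"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.reflectance.shape[1]

    def column_index(self, wavelength_nm: float, tol: float = 2.0) -> int:
        """Index of the grid column nearest ``wavelength_nm`` within ``tol`` nm."""
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
        if abs(self.wavelengths[idx] - wavelength_nm) > tol:
            raise KeyError(
                f"no wavelength within {tol} nm of {wavelength_nm} nm "
                f"(grid spans {self.wavelengths[0]:g}-{self.wavelengths[-1]:g} nm)"
            )
        return idx

    def select_rows(self, index: np.ndarray) -> "SpectralDataset":
        return replace(
            self,
            reflectance=self.reflectance[index],
            np_percent=self.np_percent[index],
            sfp_percent=self.sfp_percent[index],
            cf_percent=self.cf_percent[index],
            treatment_id=self.treatment_id[index],
        )

    def select_columns(self, index: np.ndarray) -> "SpectralDataset":
        return replace(
            self,
            wavelengths=self.wavelengths[index],
            reflectance=self.reflectance[:, index],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        return (
            self.design_id == other.design_id
            and np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.reflectance, other.reflectance)
            and np.array_equal(self.np_percent, other.np_percent)
            and np.array_equal(self.sfp_percent, other.sfp_percent)
            and np.array_equal(self.cf_percent, other.cf_percent)
            and np.array_equal(self.treatment_id, other.treatment_id)
        )


@dataclass(frozen=True)
class BandDefinition:
    """A named wavelength interval with its expected variable count.

    ``lower_inclusive`` resolves boundary ownership: the 700 nm column
    belongs to VIS, so SNIR is lower-open.
    """

    name: str
    lower_nm: float
    upper_nm: float
    n_points: int
    lower_inclusive: bool = True

    def contains(self, wavelengths: np.ndarray) -> np.ndarray:
        lower = (
            wavelengths >= self.lower_nm
            if self.lower_inclusive
            else wavelengths > self.lower_nm
        )
        return lower & (wavelengths <= self.upper_nm)


BANDS: dict[str, BandDefinition] = {
    "VIS": BandDefinition("VIS", 360.0, 700.0, 328),
    "SNIR": BandDefinition("SNIR", 700.0, 1040.0, 378, lower_inclusive=False),
    "LNIR": BandDefinition("LNIR", 937.0, 2500.0, 241),
}


def subset_band(dataset: SpectralDataset, band: BandDefinition | str) -> SpectralDataset:
    """Restrict a dataset to the columns inside ``band``, in original order.

    Concentration and label vectors are unchanged.  Raises ``ValueError``
    if the band does not overlap the dataset's grid.
    """
    if isinstance(band, str):
        band = BANDS[band.upper()]
    mask = band.contains(dataset.wavelengths)
    if not mask.any():
        raise ValueError(
            f"band {band.name} [{band.lower_nm:g}, {band.upper_nm:g}] nm selects no "
            f"columns from grid spanning {dataset.wavelengths[0]:g}-"
            f"{dataset.wavelengths[-1]:g} nm"
        )
    return dataset.select_columns(np.flatnonzero(mask))


# -- plain-text I/O --------------------------------------------------------

#: Significant digits used when serializing numbers.
N_SIG_DIGITS = 10


def write_dataset(dataset: SpectralDataset, path: str | Path) -> None:
    """Write the CSV dialect: metadata columns then one column per wavelength.

    Header: ``design_id,treatment_id,np_percent,sfp_percent,cf_percent,<λ1>,...``
    with numbers at 10 significant digits.
    """
    fmt = f"{{:.{N_SIG_DIGITS - 1}e}}"

    def num(x: float) -> str:
        return fmt.format(float(x))

    lines = [",".join(META_COLUMNS + tuple(num(w) for w in dataset.wavelengths))]
    for i in range(dataset.n_samples):
        row = [
            dataset.design_id,
            str(int(dataset.treatment_id[i])),
            num(dataset.np_percent[i]),
            num(dataset.sfp_percent[i]),
            num(dataset.cf_percent[i]),
        ]
        row.extend(num(v) for v in dataset.reflectance[i])
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_dataset(path: str | Path) -> SpectralDataset:
    """Read the CSV dialect written by :func:`write_dataset`.

    Raises :class:`SpectralIOError` on a non-monotone wavelength header,
    a row whose length does not match the header, or a missing metadata
    column.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise SpectralIOError(f"{path}: empty file")
    header = lines[0].split(",")
    if tuple(header[: len(META_COLUMNS)]) != META_COLUMNS:
        missing = [c for c in META_COLUMNS if c not in header[: len(META_COLUMNS)]]
        raise SpectralIOError(
            f"{path}: missing or misordered metadata columns {missing or list(META_COLUMNS)}; "
            f"expected header to start with {','.join(META_COLUMNS)}"
        )
    try:
        wavelengths = np.array([float(w) for w in header[len(META_COLUMNS):]])
    except ValueError as exc:
        raise SpectralIOError(f"{path}: non-numeric wavelength in header: {exc}") from exc
    if wavelengths.size == 0:
        raise SpectralIOError(f"{path}: header carries no wavelength columns")
    if np.any(np.diff(wavelengths) <= 0):
        raise SpectralIOError(
            f"{path}: wavelength header is not strictly increasing (duplicate or "
            "out-of-order column)"
        )

    n_cols = len(header)
    design_ids: set[str] = set()
    treatment, np_p, sfp_p, cf_p, rows = [], [], [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != n_cols:
            raise SpectralIOError(
                f"{path}: line {lineno} has {len(cells)} fields, expected {n_cols}"
            )
        design_ids.add(cells[0])
        treatment.append(int(cells[1]))
        np_p.append(float(cells[2]))
        sfp_p.append(float(cells[3]))
        cf_p.append(float(cells[4]))
        rows.append([float(v) for v in cells[5:]])
    if len(design_ids) > 1:
        raise SpectralIOError(f"{path}: mixed design_id values {sorted(design_ids)}")
    return SpectralDataset(
        wavelengths=wavelengths,
        reflectance=np.array(rows, dtype=float),
        np_percent=np.array(np_p),
        sfp_percent=np.array(sfp_p),
        cf_percent=np.array(cf_p),
        treatment_id=np.array(treatment, dtype=int),
        design_id=design_ids.pop() if design_ids else "A",
    )
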