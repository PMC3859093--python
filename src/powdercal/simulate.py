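"""Synthetic Vis-NIR reflectance mixtures of NP with SFP and CF adulterants.

The generator emulates the statistical structure the calibration methods
face on real powder spectra: three near-collinear pure-component spectra
(all three powders are organic with similar bonds, so their profiles
overlap strongly), mixed linearly by mass fraction, then degraded by a
per-sample multiplicative scatter factor, a linear baseline, and additive
noise.  Pure spectra are sums of Gaussian absorption dips on a flat
reflectance background, with dips at the classical overtone positions
(980, 1225, 1450, 2140, 2380, 2488 nm and a visible colour band at
450 nm).

Three mixture designs are laid out:

* Design A — NP + SFP at 0/5/10/15/20 % adulterant (5 treatments),
* Design B — NP + CF likewise,
* Design C — NP + both, SFP x CF over {5, 10, 15}² (9 treatments),

each treatment with 20 samples, giving 100/100/180 samples.

Component contrasts are deliberately band-dependent: NP differs from each
single adulterant everywhere, but the two adulterant difference spectra
are collinear below ~1040 nm and only become linearly well-separated in
the long-wave NIR.  Quantifying NP in the two-adulterant design is
therefore much harder on VIS/SNIR than on LNIR, mirroring the physics
(hydrogen-bond overtone information lives in the long-wave region).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SpectralDataset

__all__ = [
    "ComponentSpectrumSpec",
    "NoiseModel",
    "DesignSpec",
    "component_spectrum",
    "generate_design",
    "default_components",
    "design_spec",
    "vis_grid",
    "snir_grid",
    "lnir_grid",
    "vis_snir_grid",
    "band_grid",
]


# -- default wavelength grids ---------------------------------------------

def vis_grid() -> np.ndarray:
    """328 uniformly spaced points on [360, 700] nm."""
    return np.linspace(360.0, 700.0, 328)


def snir_grid() -> np.ndarray:
    """378 uniformly spaced points on (700, 1040] nm."""
    return np.linspace(700.0, 1040.0, 379)[1:]


def lnir_grid() -> np.ndarray:
    """241 uniformly spaced points on [937, 2500] nm."""
    return np.linspace(937.0, 2500.0, 241)


def vis_snir_grid() -> np.ndarray:
    """Combined 360–1040 nm grid (328 + 378 points) of the first instrument."""
    return np.concatenate([vis_grid(), snir_grid()])


def band_grid(band: str) -> np.ndarray:
    """Default grid for a band name (``VIS``, ``SNIR``, ``LNIR``)."""
    grids = {"VIS": vis_grid, "SNIR": snir_grid, "LNIR": lnir_grid}
    try:
        return grids[band.upper()]()
    except KeyError:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(grids)}") from None


# -- component spectra ----------------------------------------------------

@dataclass(frozen=True)
class ComponentSpectrumSpec:
    """Pure-component reflectance: flat background minus Gaussian dips.

    ``bands`` is a list of ``(center_nm, width_nm, depth)`` triples; the
    reflectance at wavelength λ is

        R(λ) = base_reflectance − Σ_b depth_b · exp(−(λ − c_b)² / (2 w_b²)),

    clipped to [0, 1].
    """

    component: str
    bands: tuple[tuple[float, float, float], ...]
    base_reflectance: float = 0.65

    def __post_init__(self) -> None:
        if not 0.0 < self.base_reflectance <= 1.0:
            raise ValueError("base_reflectance must lie in (0, 1]")
        for center, width, depth in self.bands:
            if depth < 0:
                raise ValueError(f"band at {center} nm has negative depth {depth}")
            if width <= 0:
                raise ValueError(f"band at {center} nm has non-positive width {width}")


def component_spectrum(spec: ComponentSpectrumSpec, grid: np.ndarray) -> np.ndarray:
    """Evaluate a pure-component spectrum on a strictly increasing grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or (grid.size > 1 and np.any(np.diff(grid) <= 0)):
        raise ValueError("grid must be a strictly increasing 1-D vector")
    r = np.full(grid.shape, spec.base_reflectance)
    for center, width, depth in spec.bands:
        r -= depth * np.exp(-((grid - center) ** 2) / (2.0 * width**2))
    return np.clip(r, 0.0, 1.0)


# Default pure-component band tables (center nm, width nm, depth).
#
# Shared centers with component-specific depths keep the pure spectra
# highly correlated (>0.95 on the LNIR grid) while leaving enough linear
# contrast for calibration.  Depth contrasts are scaled so full-spectrum
# PLSR on Design A under default noise performs near r_P ~ 0.9 rather than
# perfectly.  Below 1040 nm the two adulterant contrasts (NP−SFP, NP−CF)
# are proportional, so the two-adulterant design is nearly unidentifiable
# there; in LNIR they are well separated.
_NP_BANDS = (
    (450.0, 40.0, 0.180),
    (550.0, 60.0, 0.050),
    (840.0, 50.0, 0.050),
    (980.0, 30.0, 0.060),
    (1225.0, 35.0, 0.077),
    (1450.0, 45.0, 0.171),
    (1940.0, 80.0, 0.300),
    (2140.0, 50.0, 0.091),
    (2380.0, 35.0, 0.073),
    (2488.0, 25.0, 0.096),
)
_SFP_BANDS = (
    (450.0, 40.0, 0.210),
    (550.0, 60.0, 0.050),
    (840.0, 50.0, 0.080),
    (980.0, 30.0, 0.050),
    (1225.0, 35.0, 0.103),
    (1450.0, 45.0, 0.119),
    (1940.0, 80.0, 0.300),
    (2140.0, 50.0, 0.143),
    (2380.0, 35.0, 0.047),
    (2488.0, 25.0, 0.070),
)
_CF_BANDS = (
    (450.0, 40.0, 0.150),
    (550.0, 60.0, 0.050),
    (840.0, 50.0, 0.020),
    (980.0, 30.0, 0.070),
    (1225.0, 35.0, 0.044),
    (1450.0, 45.0, 0.104),
    (1940.0, 80.0, 0.300),
    (2140.0, 50.0, 0.113),
    (2380.0, 35.0, 0.106),
    (2488.0, 25.0, 0.046),
)


def default_components() -> tuple[ComponentSpectrumSpec, ...]:
    """Default (NP, SFP, CF) pure-component specs."""
    return (
        ComponentSpectrumSpec("NP", _NP_BANDS),
        ComponentSpectrumSpec("SFP", _SFP_BANDS),
        ComponentSpectrumSpec("CF", _CF_BANDS),
    )


# -- noise and designs ----------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Per-sample instrument noise applied to mixture spectra.

    All scales are fabricated stand-ins (no repeatability figures exist
    for the measured spectra, which averaged 10 successive scans); they
    are tunable and documented in docs/methods.md.

    additive_sd
        i.i.d. Gaussian noise per wavelength, reflectance units.
    multiplicative_sd
        sd of the per-sample scatter factor m ~ N(1, sd).
    baseline_slope_sd
        sd of the per-sample linear baseline slope, reflectance per nm.
    baseline_offset_sd
        sd of the per-sample constant baseline offset, reflectance units.
    """

    additive_sd: float = 0.005
    multiplicative_sd: float = 0.01
    baseline_slope_sd: float = 1e-5
    baseline_offset_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "multiplicative_sd", "baseline_slope_sd",
                     "baseline_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DesignSpec:
    """A mixture design: treatments as (NP%, SFP%, CF%) by mass."""

    design_id: str
    treatments: tuple[tuple[float, float, float], ...]
    samples_per_treatment: int = 20

    def __post_init__(self) -> None:
        if self.samples_per_treatment < 1:
            raise ValueError("samples_per_treatment must be >= 1")
        for t, (np_pct, sfp_pct, cf_pct) in enumerate(self.treatments, start=1):
            if abs(np_pct + sfp_pct + cf_pct - 100.0) > 1e-9:
                raise ValueError(
                    f"treatment {t} fractions sum to {np_pct + sfp_pct + cf_pct}, "
                    "expected 100"
                )

    @property
    def n_samples(self) -> int:
        return len(self.treatments) * self.samples_per_treatment


_ADULTERANT_LEVELS = (0.0, 5.0, 10.0, 15.0, 20.0)


def design_spec(design_id: str, samples_per_treatment: int = 20) -> DesignSpec:
    """Standard design: A = NP+SFP, B = NP+CF, C = NP+SFP+CF (3x3 grid)."""
    d = design_id.upper()
    if d == "A":
        treatments = tuple((100.0 - s, s, 0.0) for s in _ADULTERANT_LEVELS)
    elif d == "B":
        treatments = tuple((100.0 - c, 0.0, c) for c in _ADULTERANT_LEVELS)
    elif d == "C":
        treatments = tuple(
            (100.0 - s - c, s, c) for s in (5.0, 10.0, 15.0) for c in (5.0, 10.0, 15.0)
        )
    else:
        raise ValueError(f"unknown design {design_id!r}; expected A, B or C")
    return DesignSpec(d, treatments, samples_per_treatment)


def generate_design(
    design: DesignSpec | str,
    components: tuple[ComponentSpectrumSpec, ...] | None = None,
    noise: NoiseModel | None = None,
    grid: np.ndarray | None = None,
) -> SpectralDataset:
    """Simulate a full design on ``grid`` (default: LNIR grid).

    Each sample i of a treatment with mass fractions (f_NP, f_SFP, f_CF)
    has

        R_i(λ) = m_i · Σ_c f_c · R_c(λ) + β0_i + β1_i (λ − λ̄) + ε_i(λ)

    with m_i ~ N(1, multiplicative_sd), β0_i ~ N(0, baseline_offset_sd),
    β1_i ~ N(0, baseline_slope_sd) and ε i.i.d. N(0, additive_sd), then
    clipped to [0, 1].  Fully reproducible from ``noise.seed``.
    """
    if isinstance(design, str):
        design = design_spec(design)
    if components is None:
        components = default_components()
    if noise is None:
        noise = NoiseModel()
    if grid is None:
        grid = lnir_grid()
    grid = np.asarray(grid, dtype=float)
    if len(components) != 3:
        raise ValueError("components must be the (NP, SFP, CF) triple")

    pure = np.stack([component_spectrum(c, grid) for c in components])  # (3, p)
    lam_centered = grid - grid.mean()
    rng = np.random.default_rng(noise.seed)

    rows, np_p, sfp_p, cf_p, tid = [], [], [], [], []
    for t, fractions in enumerate(design.treatments, start=1):
        mix = np.asarray(fractions) @ pure / 100.0
        for _ in range(design.samples_per_treatment):
            m = rng.normal(1.0, noise.multiplicative_sd)
            beta0 = rng.normal(0.0, noise.baseline_offset_sd)
            beta1 = rng.normal(0.0, noise.baseline_slope_sd)
            eps = rng.normal(0.0, noise.additive_sd, size=grid.size)
            rows.append(np.clip(m * mix + beta0 + beta1 * lam_centered + eps, 0.0, 1.0))
            np_p.append(fractions[0])
            sfp_p.append(fractions[1])
            cf_p.append(fractions[2])
            tid.append(t)

    return SpectralDataset(
        wavelengths=grid,
        reflectance=np.array(rows),
        np_percent=np.array(np_p),
        sfp_percent=np.array(sfp_p),
        cf_percent=np.array(cf_p),
        treatment_id=np.array(tid, dtype=int),
        design_id=design.design_id,
    )
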