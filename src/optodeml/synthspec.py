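"""Physics-based forward model of a dual-analyte (pH / dissolved O2) optode.

The simulated sensor is a two-layer luminescent film read out with a
hyperspectral camera: a pH-sensitive top layer whose indicator exists in an
acid and a base emission form (governed by a Boltzmann sigmoid centred at the
apparent pKa, with an isosbestic crossing near 530 nm), an analyte-insensitive
reference dye emitting between 500 and 600 nm, and an O2-sensitive
phosphor emitting near 770 nm whose intensity is quenched according to the
simplified Stern-Volmer law.  The two layers are optically coupled: part of
the acid-form emission is reabsorbed by the O2 layer (strongest under anoxia,
when that layer's ground-state absorption is largest), and part of the
reference emission is reabsorbed by the base form of the pH indicator.  These
inner-filter cross-talk terms are what make naive single-analyte Boltzmann /
Stern-Volmer calibrations fail and motivate the supervised cascade model.

Every emission band is modelled as a unit-height Gaussian on the wavelength
grid; per-pixel noise is additive Gaussian, clipped at zero.  All stochastic
functions take explicit seeds; there is no hidden global RNG state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cube_io import CalibrationTable, SpectralCube
from .chemimage import ChemicalImage

__all__ = [
    "WavelengthGrid",
    "Band",
    "SpectralModelParams",
    "SceneSpec",
    "boltzmann_fraction",
    "stern_volmer_intensity",
    "emit_spectrum",
    "emit_components",
    "generate_calibration_cube",
    "generate_calibration_set",
    "generate_gradient_scene",
    "imbalanced_counts",
    "AIR_SATURATION_HPA",
]

#: O2 partial pressure of air-saturated buffer under the calibration
#: conditions (22.5 degC, ambient pressure), in hPa.
AIR_SATURATION_HPA = 195.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered emission-band centres, in nm.

    The default grid mirrors the camera acquisition: 470-900 nm at a 3 nm
    pixel step, i.e. 144 bands starting at 470 nm with the last band at
    899 nm (bands never exceed ``stop``).
    """

    start: float = 470.0
    stop: float = 900.0
    step: float = 3.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.stop <= self.start:
            raise ValueError("stop must exceed start")

    @property
    def values(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Band:
    """One Gaussian emission band: unit-height profile scaled by amplitude."""

    center: float  # nm
    width: float  # Gaussian sigma, nm
    amplitude: float  # a.u.

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band width must be positive, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        """Unit-height Gaussian evaluated on the wavelength axis."""
        return np.exp(-((wavelengths - self.center) ** 2) / (2.0 * self.width**2))


def _default_base_amplitude(
    acid: Band, ref: Band, crosstalk_acid: float, crosstalk_ref: float
) -> float:
    """Base-form amplitude that pins the isosbestic crossing to 530 nm.

    The pH-dependent part of the spectrum at fixed pO2 is
    f * [A_b G_b - alpha G_a - A_ref ct_ref G_ref] with alpha the
    cross-talk-attenuated acid amplitude; all pH curves therefore share an
    exact crossing where the bracket vanishes.  Solving the bracket = 0 at
    530 nm and 0 hPa (anoxia, where the acid attenuation is strongest) gives
    the amplitude below.
    """
    lam = np.array([530.0])
    g_a = float(acid.profile(lam)[0])
    g_r = float(ref.profile(lam)[0])
    g_b = float(np.exp(-((530.0 - 548.0) ** 2) / (2.0 * 30.0**2)))
    alpha = acid.amplitude * (1.0 - crosstalk_acid)
    return (alpha * g_a + ref.amplitude * crosstalk_ref * g_r) / g_b


@dataclass(frozen=True)
class SpectralModelParams:
    """All physical constants of the forward simulator.

    Defaults describe a sensor with a pKa of 7.0 and a usable dynamic range
    of pKa +/- 2 (pH 5-9), an O2 phosphor with K_SV = 0.01 / hPa (about
    one-third of the unquenched intensity left at air saturation, 195 hPa),
    and cross-talk coefficients chosen so that single-analyte calibration
    fits visibly fail, which is the regime the cascade model is built for.
    The base-band amplitude is solved in closed form so the acid/base
    emission curves cross at the 530 nm isosbestic point.
    """

    pKa: float = 7.0
    boltzmann_slope: float = 1.0  # pH units; range ~pKa +/- 2 for slope 1
    acid_band: Band = field(default_factory=lambda: Band(490.0, 25.0, 1.0))
    base_band: Band | None = None  # None -> amplitude solved for 530 nm crossing
    ref_band: Band = field(default_factory=lambda: Band(535.0, 28.0, 0.6))
    o2_band: Band = field(default_factory=lambda: Band(770.0, 20.0, 1.0))
    K_SV: float = 0.01  # 1/hPa
    crosstalk_acid: float = 0.30  # fraction of acid emission lost to the O2 layer
    crosstalk_ref: float = 0.15  # fraction of reference emission lost to the base form
    noise_sd: float = 0.02  # a.u., additive Gaussian per band

    def __post_init__(self) -> None:
        if self.boltzmann_slope == 0:
            raise ValueError("boltzmann_slope must be nonzero")
        if self.K_SV < 0:
            raise ValueError(f"K_SV must be >= 0, got {self.K_SV}")
        if not (0.0 <= self.crosstalk_acid <= 1.0):
            raise ValueError("crosstalk_acid must lie in [0, 1]")
        if not (0.0 <= self.crosstalk_ref <= 1.0):
            raise ValueError("crosstalk_ref must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.base_band is None:
            amp = _default_base_amplitude(
                self.acid_band, self.ref_band, self.crosstalk_acid, self.crosstalk_ref
            )
            object.__setattr__(self, "base_band", Band(548.0, 30.0, amp))


@dataclass(frozen=True)
class SceneSpec:
    """Ground-truth analyte fields for a simulated scene.

    ``ph_field`` and ``po2_field`` may be scalars (homogeneous scene) or
    per-pixel arrays of shape (height, width).
    """

    height: int
    width: int
    ph_field: float | np.ndarray
    po2_field: float | np.ndarray
    seed: int = 0

    def fields(self) -> tuple[np.ndarray, np.ndarray]:
        shape = (self.height, self.width)
        ph = np.broadcast_to(np.asarray(self.ph_field, dtype=float), shape)
        po2 = np.broadcast_to(np.asarray(self.po2_field, dtype=float), shape)
        for name, arr in (("ph_field", ph), ("po2_field", po2)):
            src = np.asarray(getattr(self, name), dtype=float)
            if src.ndim and src.shape != shape:
                raise ValueError(
                    f"{name} shape {src.shape} does not match scene {shape}"
                )
        if not np.all(np.isfinite(ph)):
            raise ValueError("ph_field must be finite")
        if not np.all(po2 >= 0):
            raise ValueError("po2_field must be >= 0")
        return np.ascontiguousarray(ph), np.ascontiguousarray(po2)


def boltzmann_fraction(ph, pKa: float, slope: float):
    """Fraction of the pH indicator in its base form.

    Base-10 logistic ``f = 1 / (1 + 10**((pKa - ph) / slope))``: the sigmoid
    midpoint sits at the pKa and, for slope 1, the response saturates over
    roughly pKa +/- 2 pH units (the sensor's dynamic range).
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    ph = np.asarray(ph, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** ((pKa - ph) / slope))
    return out if out.ndim else float(out)


def stern_volmer_intensity(I0, K_SV: float, po2):
    """Quenched phosphorescence intensity under the simplified Stern-Volmer law.

    ``I = I0 / (1 + K_SV * pO2)``; K_SV in 1/hPa, pO2 in hPa.
    """
    if np.any(np.asarray(I0) < 0):
        raise ValueError("I0 must be >= 0")
    if K_SV < 0:
        raise ValueError("K_SV must be >= 0")
    if np.any(np.asarray(po2) < 0):
        raise ValueError("po2 must be >= 0")
    po2 = np.asarray(po2, dtype=float)
    out = np.asarray(I0, dtype=float) / (1.0 + K_SV * po2)
    return out if out.ndim else float(out)


def emit_components(
    ph,
    po2,
    params: SpectralModelParams | None = None,
    grid: WavelengthGrid | None = None,
) -> dict[str, np.ndarray]:
    """Per-band contribution of each dye to the noiseless emission spectrum.

    ``ph`` and ``po2`` may be scalars or equal-shape arrays; components then
    have shape ``ph.shape + (n_bands,)``.  Keys: acid, base, ref, o2.
    """
    params = params or SpectralModelParams()
    grid = grid or WavelengthGrid()
    lam = grid.values
    if lam.size == 0:
        raise ValueError("wavelength grid is empty")

    ph = np.asarray(ph, dtype=float)
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("po2 must be >= 0")
    f = np.asarray(boltzmann_fraction(ph, params.pKa, params.boltzmann_slope))
    # O2-layer ground-state absorption saturates with the same functional
    # form as the quenching: strongest reabsorption under anoxia.
    g = 1.0 / (1.0 + params.K_SV * po2)

    f = f[..., None]
    g = np.asarray(g)[..., None]
    acid = (
        (1.0 - f)
        * params.acid_band.amplitude
        * (1.0 - params.crosstalk_acid * g)
        * params.acid_band.profile(lam)
    )
    base = f * params.base_band.amplitude * params.base_band.profile(lam)
    ref = (
        params.ref_band.amplitude
        * (1.0 - params.crosstalk_ref * f)
        * params.ref_band.profile(lam)
    )
    o2 = (
        np.asarray(
            stern_volmer_intensity(params.o2_band.amplitude, params.K_SV, po2)
        )[..., None]
        * params.o2_band.profile(lam)
    )
    return {"acid": acid, "base": base, "ref": ref, "o2": o2}


def emit_spectrum(
    ph,
    po2,
    params: SpectralModelParams | None = None,
    grid: WavelengthGrid | None = None,
) -> np.ndarray:
    """Noiseless emission spectrum of the dual-analyte optode.

    Sum of the four Gaussian band contributions (acid and base forms of the
    pH indicator, reference dye, O2 phosphor) including the inner-filter
    cross-talk terms.  Intensities are nonnegative; the O2-band intensity is
    strictly decreasing in pO2 at fixed pH.
    """
    comps = emit_components(ph, po2, params, grid)
    return comps["acid"] + comps["base"] + comps["ref"] + comps["o2"]


def generate_calibration_cube(
    ph: float,
    po2: float,
    params: SpectralModelParams | None = None,
    grid: WavelengthGrid | None = None,
    shape: tuple[int, int] = (25, 25),
    seed: int = 0,
) -> tuple[SpectralCube, dict]:
    """Simulate one calibration image acquisition at a fixed (pH, pO2).

    Every pixel carries the same noiseless spectrum plus i.i.d. Gaussian
    noise of sd ``params.noise_sd``, clipped at zero.  The frame must be at
    least 5x5 so at least one RoI tile fits.
    """
    params = params or SpectralModelParams()
    grid = grid or WavelengthGrid()
    h, w = shape
    if h < 5 or w < 5:
        raise ValueError(f"cube shape {shape} is smaller than one 5x5 RoI tile")
    base = emit_spectrum(ph, po2, params, grid)
    rng = np.random.default_rng(seed)
    data = base[None, None, :] + rng.normal(0.0, params.noise_sd, (h, w, len(base)))
    np.clip(data, 0.0, None, out=data)
    cube = SpectralCube(
        data=data,
        wavelengths=grid.values,
        metadata={"ph": float(ph), "po2": float(po2), "seed": int(seed)},
    )
    return cube, {"ph": float(ph), "po2": float(po2), "seed": int(seed)}


def imbalanced_counts(
    ph_points, po2_points, base: int = 10, boost: int = 6
) -> dict[tuple[float, float], int]:
    """Per-calibration-point sample budgets with a realistic imbalance.

    Calibration campaigns dwell longest at anoxia and air saturation (the
    endpoints used to bracket every pH series), so those O2 points receive
    ``boost`` times the base budget; all other points get ``base`` samples.
    """
    counts = {}
    for ph in ph_points:
        for po2 in po2_points:
            extreme = po2 == 0 or abs(po2 - AIR_SATURATION_HPA) < 1e-9
            counts[(float(ph), float(po2))] = base * (boost if extreme else 1)
    return counts


def generate_calibration_set(
    ph_points,
    po2_points,
    counts: int | dict[tuple[float, float], int] | str = 10,
    params: SpectralModelParams | None = None,
    grid: WavelengthGrid | None = None,
    seed: int = 0,
) -> CalibrationTable:
    """Draw a labeled calibration table over a (pH, pO2) grid.

    ``counts`` is a uniform per-point budget, an explicit per-point mapping,
    or the string ``"imbalanced"`` for the preset that overweights anoxic
    and air-saturated points.  Each row is the noiseless spectrum plus
    Gaussian noise (sd ``params.noise_sd``), clipped at zero.
    """
    params = params or SpectralModelParams()
    grid = grid or WavelengthGrid()
    ph_points = [float(p) for p in ph_points]
    po2_points = [float(p) for p in po2_points]
    if not ph_points or not po2_points:
        raise ValueError("ph_points and po2_points must be nonempty")
    if counts == "imbalanced":
        counts = imbalanced_counts(ph_points, po2_points)
    if isinstance(counts, int):
        counts = {(ph, po2): counts for ph in ph_points for po2 in po2_points}

    rng = np.random.default_rng(seed)
    lam = grid.values
    spectra, phs, po2s, prov = [], [], [], []
    for ph in ph_points:
        for po2 in po2_points:
            n = int(counts.get((ph, po2), 0))
            if n == 0:
                continue
            clean = emit_spectrum(ph, po2, params, grid)
            noisy = clean[None, :] + rng.normal(0.0, params.noise_sd, (n, lam.size))
            np.clip(noisy, 0.0, None, out=noisy)
            spectra.append(noisy)
            phs.extend([ph] * n)
            po2s.extend([po2] * n)
            prov.extend(f"synth:pH{ph:g}:pO2{po2:g}:{i}" for i in range(n))
    if not spectra:
        warnings.warn("zero sample budget: returning an empty calibration table")
        return CalibrationTable(
            spectra=np.empty((0, lam.size)),
            wavelengths=lam,
            ph=np.empty(0),
            po2=np.empty(0),
            provenance=np.empty(0, dtype=object),
        )
    return CalibrationTable(
        spectra=np.vstack(spectra),
        wavelengths=lam,
        ph=np.asarray(phs),
        po2=np.asarray(po2s),
        provenance=np.asarray(prov, dtype=object),
    )


def generate_gradient_scene(
    spec: SceneSpec,
    params: SpectralModelParams | None = None,
    grid: WavelengthGrid | None = None,
) -> tuple[SpectralCube, ChemicalImage]:
    """Simulate a scene with spatially varying analytes plus its ground truth.

    Returns the noisy cube and a pixel-aligned ChemicalImage holding the true
    pH / pO2 maps; the validity mask applies the pH 5-9 dynamic-range rule.
    """
    params = params or SpectralModelParams()
    grid = grid or WavelengthGrid()
    ph, po2 = spec.fields()
    data = emit_spectrum(ph, po2, params, grid)
    rng = np.random.default_rng(spec.seed)
    data = data + rng.normal(0.0, params.noise_sd, data.shape)
    np.clip(data, 0.0, None, out=data)
    cube = SpectralCube(
        data=data, wavelengths=grid.values, metadata={"seed": int(spec.seed)}
    )
    truth = ChemicalImage(
        ph_map=ph.copy(),
        po2_map=po2.copy(),
        valid_mask=(ph >= 5.0) & (ph <= 9.0),
        provenance={"source": "synthetic ground truth", "seed": int(spec.seed)},
    )
    return cube, truth


def with_crosstalk(params: SpectralModelParams, acid: float, ref: float):
    """Copy of ``params`` with the cross-talk coefficients replaced."""
    return replace(params, crosstalk_acid=acid, crosstalk_ref=ref, base_band=None)
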