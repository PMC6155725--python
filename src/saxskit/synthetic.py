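"""Seeded synthetic scattering profiles on the laboratory instrument grid.

Emulates the measurement geometry of a Cu K-alpha pinhole camera
(wavelength 0.154 nm, q = 0.142-2.844 nm^-1) and the statistical structure
the analysis assumes: composite curves built from the published
per-concentration parameter table for the cellulose/[Emim][OAc] series
(two Guinier-Porod aggregates plus a Porod shoulder at high concentration,
a single aggregate at 30-40 mol %), replicate measurements with noise
(3 replicates above 40 mol %, 1 otherwise), and an additive Kapton-like
background curve for exercising background subtraction.

The published table reports no forward intensities; the generator's stated
amplitude convention is i0_large = 1.0, i0_small = 0.5, and a shoulder
prefactor chosen so the shoulder contributes 20% of the total intensity at
q_min.  Default noise is 2% multiplicative Gaussian, a typical
laboratory-source figure.  All randomness is driven by explicit seeds and
is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .models import (
    CompositeModel,
    DebyeBuecheParams,
    GuinierPorodParams,
    OrnsteinZernikeParams,
    PorodParams,
    composite_intensity,
    debye_bueche_intensity,
    gel_intensity,
    ornstein_zernike_intensity,
    porod_intensity,
)
from .models import GelModel
from .profiles import ScatteringProfile

__all__ = [
    "InstrumentConfig",
    "NoiseModel",
    "SERIES_SHAPE_PARAMS",
    "DEFAULT_AMPLITUDES",
    "make_q_grid",
    "model_curve",
    "build_concentration_model",
    "simulate_profile",
    "simulate_concentration_series",
    "simulate_background",
]

# Fitted shape parameters of the cellulose/[Emim][OAc] concentration series
# (mol % -> large aggregate (rg1, d1, s1), small aggregate (rg2, d2, s2),
# shoulder exponent ds; None where the component is absent).
SERIES_SHAPE_PARAMS: dict[int, dict[str, float | None]] = {
    30: dict(rg1=7.9, d1=4.0, s1=0.0, rg2=None, d2=None, s2=None, ds=None),
    35: dict(rg1=7.5, d1=3.8, s1=0.0, rg2=None, d2=None, s2=None, ds=None),
    40: dict(rg1=7.1, d1=3.9, s1=0.0, rg2=None, d2=None, s2=None, ds=None),
    50: dict(rg1=5.5, d1=3.0, s1=0.0, rg2=1.6, d2=3.5, s2=0.0, ds=4.0),
    60: dict(rg1=5.9, d1=4.0, s1=0.0, rg2=1.6, d2=4.0, s2=0.1, ds=4.0),
    70: dict(rg1=4.9, d1=3.6, s1=0.1, rg2=1.6, d2=4.0, s2=0.1, ds=4.0),
    80: dict(rg1=4.7, d1=3.8, s1=0.1, rg2=1.5, d2=4.0, s2=0.1, ds=4.0),
}

# Amplitude convention (forward intensities are not published).
DEFAULT_AMPLITUDES: dict[str, float] = {
    "i0_large": 1.0,
    "i0_small": 0.5,
    "shoulder_fraction": 0.2,  # of total intensity at q_min
}


@dataclass(frozen=True)
class InstrumentConfig:
    """Q-grid geometry of the emulated instrument."""

    q_min: float = 0.142
    q_max: float = 2.844
    n_points: int = 256
    spacing: str = "linear"
    wavelength: float = 0.154  # nm, metadata only

    def __post_init__(self) -> None:
        if not 0 < self.q_min < self.q_max:
            raise ValueError("require 0 < q_min < q_max")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.spacing not in ("linear", "log"):
            raise ValueError("spacing must be 'linear' or 'log'")


@dataclass(frozen=True)
class NoiseModel:
    """Noise specification: multiplicative Gaussian (``level`` = relative
    sd) or Poisson counting (``level`` = expected counts at the curve
    maximum).  Identical seeds reproduce identical profiles bit-for-bit."""

    kind: str = "multiplicative_gaussian"
    level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative_gaussian", "poisson_count"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not self.level > 0:
            raise ValueError("noise level must be positive")


def make_q_grid(config: InstrumentConfig) -> np.ndarray:
    """Strictly increasing grid spanning [q_min, q_max] inclusive."""
    if config.spacing == "log":
        return np.geomspace(config.q_min, config.q_max, config.n_points)
    return np.linspace(config.q_min, config.q_max, config.n_points)


def model_curve(model, q: np.ndarray) -> np.ndarray:
    """Evaluate any in-scope model object on q."""
    if isinstance(model, CompositeModel):
        return composite_intensity(model, q)
    if isinstance(model, GelModel):
        return gel_intensity(model, q)
    if isinstance(model, DebyeBuecheParams):
        return debye_bueche_intensity(model, q)
    if isinstance(model, OrnsteinZernikeParams):
        return ornstein_zernike_intensity(model, q)
    if isinstance(model, GuinierPorodParams):
        return composite_intensity(CompositeModel(ggp_components=(model,)), q)
    if isinstance(model, PorodParams):
        return porod_intensity(model, q)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def build_concentration_model(
    concentration: int,
    amplitudes: Mapping[str, float] | None = None,
    config: InstrumentConfig | None = None,
) -> CompositeModel:
    """Composite model for one published concentration row.

    The shoulder prefactor is chosen so that the Porod shoulder contributes
    ``shoulder_fraction`` of the *total* intensity at q_min.
    """
    if concentration not in SERIES_SHAPE_PARAMS:
        raise ValueError(
            f"unknown concentration {concentration} mol %; "
            f"valid rows: {sorted(SERIES_SHAPE_PARAMS)}"
        )
    amps = dict(DEFAULT_AMPLITUDES)
    amps.update(amplitudes or {})
    config = config or InstrumentConfig()
    row = SERIES_SHAPE_PARAMS[concentration]
    comps = [
        GuinierPorodParams(
            i0=amps["i0_large"], rg=row["rg1"], d=row["d1"], s=row["s1"]
        )
    ]
    if row["rg2"] is not None:
        comps.append(
            GuinierPorodParams(
                i0=amps["i0_small"], rg=row["rg2"], d=row["d2"], s=row["s2"]
            )
        )
    shoulder = None
    if row["ds"] is not None:
        frac = amps["shoulder_fraction"]
        ggp_at_qmin = float(
            composite_intensity(
                CompositeModel(ggp_components=tuple(comps)),
                np.array([config.q_min]),
            )[0]
        )
        # shoulder = frac * total  =>  shoulder = frac/(1-frac) * ggp_sum
        target = frac / (1.0 - frac) * ggp_at_qmin
        shoulder = PorodParams(prefactor=target * config.q_min ** row["ds"], d=row["ds"])
    return CompositeModel(ggp_components=tuple(comps), porod_shoulder=shoulder)


def simulate_profile(
    model,
    config: InstrumentConfig | None = None,
    noise: NoiseModel | None = None,
    label: str = "",
    concentration: float | None = None,
    background: np.ndarray | None = None,
) -> ScatteringProfile:
    """Simulate one measurement of ``model`` on the instrument grid.

    ``noise=None`` gives the noiseless model curve (no sigma column).
    Gaussian noise multiplies each point by (1 + level * N(0,1)); Poisson
    noise draws counts scaled so the curve maximum has ``level`` expected
    counts, then rescales back.  The sigma column carries the true
    per-point standard deviation in both cases.

    ``background``, when given, is an additive deterministic curve on the
    same grid (e.g. window scattering) included *before* noise — the
    measured pattern then contains it, as in a real experiment, and
    background subtraction downstream is meaningful.
    """
    config = config or InstrumentConfig()
    q = make_q_grid(config)
    curve = model_curve(model, q)
    if background is not None:
        background = np.asarray(background, dtype=float)
        if background.shape != q.shape:
            raise ValueError("background curve must match the q grid")
        curve = curve + background
    if noise is None:
        return ScatteringProfile(
            q=q, intensity=curve, sigma=None, label=label, concentration=concentration
        )
    rng = np.random.default_rng(noise.seed)
    if noise.kind == "multiplicative_gaussian":
        sigma = noise.level * np.abs(curve)
        intensity = curve * (1.0 + noise.level * rng.standard_normal(q.size))
    else:  # poisson_count
        scale = noise.level / float(np.max(curve))
        counts = rng.poisson(np.clip(curve * scale, 0, None))
        intensity = counts / scale
        sigma = np.sqrt(np.clip(curve * scale, 1e-12, None)) / scale
    sigma = np.clip(sigma, np.max(sigma) * 1e-12 + 1e-300, None)
    return ScatteringProfile(
        q=q,
        intensity=intensity,
        sigma=sigma,
        label=label or f"sim(seed={noise.seed})",
        concentration=concentration,
    )


def _replicate_seed(base_seed: int, concentration: int, replicate: int) -> int:
    """Deterministic per-replicate sub-seed, kept within 31 bits."""
    ss = np.random.SeedSequence([base_seed, concentration, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_concentration_series(
    amplitudes: Mapping[int, Mapping[str, float]] | None = None,
    noise: NoiseModel | None = None,
    config: InstrumentConfig | None = None,
    concentrations: list[int] | None = None,
    background: np.ndarray | None = None,
) -> dict[int, list[ScatteringProfile]]:
    """Simulate the whole concentration series with replicate structure.

    Three replicates are produced for concentrations above 40 mol %
    (mirroring the measurement protocol for inhomogeneous high-
    concentration samples), one otherwise.  ``amplitudes`` optionally maps
    concentration -> amplitude overrides; ``background`` is an additive
    deterministic curve included in every simulated measurement.
    """
    config = config or InstrumentConfig()
    noise = noise or NoiseModel()
    concentrations = (
        sorted(SERIES_SHAPE_PARAMS) if concentrations is None else list(concentrations)
    )
    out: dict[int, list[ScatteringProfile]] = {}
    for conc in concentrations:
        amps = dict((amplitudes or {}).get(conc, {}))
        model = build_concentration_model(conc, amps, config)
        n_rep = 3 if conc > 40 else 1
        reps = []
        for r in range(n_rep):
            rep_noise = NoiseModel(
                kind=noise.kind,
                level=noise.level,
                seed=_replicate_seed(noise.seed, conc, r),
            )
            reps.append(
                simulate_profile(
                    model,
                    config,
                    rep_noise,
                    label=f"sim_{conc}molpct_rep{r}",
                    concentration=float(conc),
                    background=background,
                )
            )
        out[conc] = reps
    return out


def simulate_background(
    config: InstrumentConfig | None = None,
    noise: NoiseModel | None = None,
    amplitude: float = 0.01,
) -> ScatteringProfile:
    """Smooth low-amplitude instrument/window background: a constant plus a
    weak power-law upturn at low q (Kapton-film-like), with optional noise.

    ``amplitude`` scales the whole curve; 0 gives an identically zero
    curve (and no noise is applied to it).
    """
    config = config or InstrumentConfig()
    q = make_q_grid(config)
    if amplitude == 0:
        return ScatteringProfile(q=q, intensity=np.zeros_like(q), label="background")
    curve = amplitude * (1.0 + 0.5 * (q / config.q_min) ** -1.5)
    if noise is None:
        return ScatteringProfile(q=q, intensity=curve, label="background")
    rng = np.random.default_rng(noise.seed)
    sigma = noise.level * curve
    intensity = curve * (1.0 + noise.level * rng.standard_normal(q.size))
    return ScatteringProfile(q=q, intensity=intensity, sigma=sigma, label="background")
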