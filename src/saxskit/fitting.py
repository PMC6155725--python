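"""Weighted nonlinear least-squares fitting of scattering models.

The objective is always raw intensity space:

    minimize  sum_i w_i (I_obs,i - I_model,i)^2,   w_i = 1/sigma_i^2

(unit weights when the profile carries no uncertainties).  Optimization
uses bounded trust-region least squares (`scipy.optimize.least_squares`,
method 'trf') with a numerical Jacobian; parameter standard deviations come
from the covariance of the linearized problem at the optimum, scaled by the
reduced chi-square — the conventional "nonlinear regression" error bar.

The generalized Guinier-Porod components are parameterized internally with
``delta = d - s`` (box bound delta > 0) so that the structural constraint
d > s holds at every optimizer step; the crossover q1 is therefore
recomputed from the current (rg, d, s) on every model evaluation.  Reported
estimates and standard errors are in the natural (d, s) coordinates, with
the d variance obtained by full covariance propagation.

A seeded random multistart (default 5 starts) around the initialization
mitigates local minima; the first start is always the unperturbed
initialization, so a fit started at the truth of a noise-free curve returns
the truth.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks, savgol_filter

from .exceptions import InsufficientDataError
from .models import (
    CompositeModel,
    DebyeBuecheParams,
    GelModel,
    GuinierPorodParams,
    OrnsteinZernikeParams,
    PorodParams,
    composite_intensity,
    ggp_intensity,
)
from .profiles import ScatteringProfile, kratky_transform, restrict_q

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "ModelComparison",
    "initialize_from_kratky",
    "fit_composite",
    "fit_debye_bueche",
    "fit_db_plus_oz",
    "compare_models",
    "DEFAULT_BOUNDS",
]

# Default box bounds in public parameter coordinates.  rg is capped at the
# instrument's detectable limit (~50 nm); s spans globular to nearly
# lamellar; delta = d - s keeps the crossover real.  The shoulder exponent
# defaults to the sharp-interface Porod range.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "i0": (1e-12, np.inf),
    "rg": (0.1, 50.0),
    "s": (0.0, 2.99),
    "delta": (0.01, 4.5),
    "D_s": (1e-15, np.inf),
    "ds": (3.0, 4.0),
    "background": (0.0, np.inf),
}

_MAX_NFEV = 1000
# tight enough that a noise-free synthetic curve is recovered to >= 6
# significant digits in every parameter (1e-10 falls a digit short on the
# strongly correlated shoulder/dimensionality directions)
_XTOL = 1e-15


@dataclass
class _Param:
    name: str
    value: float
    lo: float
    hi: float
    vary: bool = True


@dataclass
class FitResult:
    """Outcome of one weighted least-squares fit.

    ``estimates`` holds all model parameters (public names, d/s coordinates);
    ``stderr`` holds one entry per *free* parameter (NaN when the covariance
    is singular for that direction).  ``model`` is the fitted model object
    with estimates substituted; for composite fits its GGP components are
    ordered by descending rg (subscript 1 = larger aggregate).
    """

    model: Any
    estimates: dict[str, float]
    stderr: dict[str, float]
    chi2_reduced: float
    residuals: np.ndarray
    n_free: int
    converged: bool
    fit_window: tuple[float, float]
    extras: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "estimates": self.estimates,
            "stderr": self.stderr,
            "chi2_reduced": self.chi2_reduced,
            "n_free": self.n_free,
            "converged": self.converged,
            "fit_window": list(self.fit_window),
        }
        return json.dumps(payload, indent=2, default=float)


@dataclass
class ModelComparison:
    """Ranked model fits with a parsimony-aware selection."""

    ranked: list[FitResult]
    selected: FitResult
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# initialization

def initialize_from_kratky(
    profile: ScatteringProfile,
    n_components: int = 2,
    include_shoulder: bool | str = "auto",
    peak_prominence_frac: float = 0.02,
) -> CompositeModel:
    """Seed a composite model from the peaks of the smoothed Kratky curve.

    Each detected Kratky maximum at q_p with height k_p seeds one globular
    GGP component via the s=0 peak relation q_p = sqrt(3)/rg:

        rg = sqrt(3)/q_p,  i0 = k_p rg^2 e / 3,  d = 4,  s = 0.

    Components are extracted by iterative peak stripping: the most
    prominent maximum seeds a component, its Kratky contribution
    q^2 I_GGP(q) is subtracted, and the residual curve is searched for the
    next maximum.  This resolves a weaker scatterer that appears only as a
    shoulder on the flank of a stronger one, as happens when the two
    forward intensities are dissimilar.

    ``include_shoulder`` seeds a pure Porod term from the lowest-q points:
    ``True`` always, ``False`` never, ``"auto"`` only when the Kratky curve
    rises toward q_min (the signature of a scatterer beyond the window).
    Fewer detected peaks than requested is not an error; the model simply
    carries fewer components (logged).
    """
    if n_components not in (0, 1, 2):
        raise ValueError("n_components must be 0, 1 or 2")
    kp = kratky_transform(profile)
    k = kp.kratky
    q = kp.q
    window = min(len(k) - (1 - len(k) % 2), max(5, 2 * (len(k) // 40) + 1))
    smooth = savgol_filter(k, window_length=window, polyorder=2) if len(k) >= 7 else k
    prom_floor = peak_prominence_frac * float(np.max(smooth) - np.min(smooth))

    comps: list[GuinierPorodParams] = []
    residual = smooth.copy()
    seeded_q: list[float] = []
    for _ in range(n_components):
        peaks, props = find_peaks(residual, prominence=prom_floor)
        # residual wiggles on the flank of a stripped peak are artifacts;
        # demand clear q separation (factor 1.8) from previous seeds
        keep = [
            i
            for i, pk in enumerate(peaks)
            if all(not (qs / 1.8 <= q[pk] <= qs * 1.8) for qs in seeded_q)
        ]
        if not keep:
            break
        idx = int(peaks[keep[int(np.argmax(props["prominences"][keep]))]])
        q_p = float(q[idx])
        height = float(max(residual[idx], 1e-30))
        rg = math.sqrt(3.0) / q_p
        i0 = height * rg**2 * math.e / 3.0
        comp = GuinierPorodParams(i0=i0, rg=rg, d=4.0, s=0.0)
        comps.append(comp)
        seeded_q.append(q_p)
        residual = residual - q**2 * ggp_intensity(comp, q)
    comps.sort(key=lambda c: -c.rg)
    if len(comps) < n_components:
        logger.info(
            "Kratky initialization found %d peak(s), %d requested",
            len(comps),
            n_components,
        )

    shoulder = None
    if include_shoulder is True or (
        include_shoulder == "auto" and len(k) > 4 and smooth[0] > smooth[2] > smooth[4]
    ):
        # Porod Kratky term is D/q^2: attribute half of the lowest-q Kratky
        # value to the shoulder as a seed; the optimizer refines it.
        d_seed = 0.5 * float(max(k[0], 1e-30)) * float(q[0]) ** 2
        shoulder = PorodParams(prefactor=max(d_seed, 1e-12), d=4.0)

    if not comps and shoulder is None:
        logger.info("no Kratky peaks or shoulder detected; background-only model")
        return CompositeModel(flat_background=float(np.median(profile.intensity)))
    return CompositeModel(ggp_components=tuple(comps), porod_shoulder=shoulder)


# ---------------------------------------------------------------------------
# parameter packing

def _composite_params(
    model: CompositeModel,
    bounds: Mapping[str, tuple[float, float]] | None,
    fixed: Iterable[str] | None,
) -> list[_Param]:
    bounds = dict(bounds or {})
    fixed = set(fixed or ())

    def bound(kind: str, name: str) -> tuple[float, float]:
        return bounds.get(name, DEFAULT_BOUNDS[kind])

    params: list[_Param] = []
    for j, comp in enumerate(model.ggp_components, start=1):
        delta_fixed = f"d_{j}" in fixed  # fixing d means fixing the offset d - s
        params.append(
            _Param(f"i0_{j}", comp.i0, *bound("i0", f"i0_{j}"), f"i0_{j}" not in fixed)
        )
        params.append(
            _Param(f"rg_{j}", comp.rg, *bound("rg", f"rg_{j}"), f"rg_{j}" not in fixed)
        )
        params.append(
            _Param(f"s_{j}", comp.s, *bound("s", f"s_{j}"), f"s_{j}" not in fixed)
        )
        params.append(
            _Param(
                f"delta_{j}",
                comp.d - comp.s,
                *bound("delta", f"d_{j}"),
                not delta_fixed,
            )
        )
    if model.porod_shoulder is not None:
        params.append(
            _Param(
                "D_s",
                model.porod_shoulder.prefactor,
                *bound("D_s", "D_s"),
                "D_s" not in fixed,
            )
        )
        params.append(
            _Param("ds", model.porod_shoulder.d, *bound("ds", "ds"), "ds" not in fixed)
        )
    if model.flat_background is not None:
        params.append(
            _Param(
                "background",
                model.flat_background,
                *bound("background", "background"),
                "background" not in fixed,
            )
        )
    for p in params:
        p.value = float(np.clip(p.value, p.lo, p.hi))
    return params


def _build_composite(template: CompositeModel, values: Mapping[str, float]) -> CompositeModel:
    comps = []
    for j in range(1, len(template.ggp_components) + 1):
        s = values[f"s_{j}"]
        comps.append(
            GuinierPorodParams(
                i0=values[f"i0_{j}"],
                rg=values[f"rg_{j}"],
                d=s + values[f"delta_{j}"],
                s=s,
            )
        )
    shoulder = None
    if template.porod_shoulder is not None:
        shoulder = PorodParams(
            prefactor=values["D_s"],
            d=values["ds"],
            d_max=max(4.0, values["ds"]),
        )
    background = values.get("background")
    return CompositeModel(
        ggp_components=tuple(comps),
        porod_shoulder=shoulder,
        flat_background=background,
    )


# ---------------------------------------------------------------------------
# core least-squares driver

def _run_fit(
    profile: ScatteringProfile,
    params: list[_Param],
    predict,  # (values dict, q) -> model intensity
    n_starts: int,
    seed: int,
    window: tuple[float, float],
) -> tuple[dict[str, float], dict[str, float], float, np.ndarray, bool, np.ndarray, list[str]]:
    q, i_obs = profile.q, profile.intensity
    weights = 1.0 / profile.sigma if profile.sigma is not None else np.ones_like(q)
    free = [p for p in params if p.vary]
    fixed_vals = {p.name: p.value for p in params if not p.vary}
    free_names = [p.name for p in free]

    def residuals(x: np.ndarray) -> np.ndarray:
        values = dict(zip(free_names, x))
        values.update(fixed_vals)
        return (predict(values, q) - i_obs) * weights

    if len(q) <= len(free):
        raise InsufficientDataError(
            f"{len(q)} points cannot constrain {len(free)} free parameters"
        )

    lo = np.array([p.lo for p in free])
    hi = np.array([p.hi for p in free])
    x0 = np.array([p.value for p in free])
    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            xk = x0
        else:
            jitter = np.exp(rng.normal(0.0, 0.25, size=x0.size))
            xk = x0 * jitter + np.where(x0 == 0, rng.normal(0, 0.01, x0.size), 0.0)
            xk = np.clip(xk, lo + 1e-12 * np.maximum(np.abs(lo), 1), hi)
            xk = np.where(np.isfinite(xk), xk, x0)
        try:
            res = least_squares(
                residuals,
                xk,
                bounds=(lo, hi),
                method="trf",
                xtol=_XTOL,
                ftol=_XTOL,
                gtol=None,
                max_nfev=_MAX_NFEV,
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("fit start %d failed: %s", start, exc)
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")

    values = dict(zip(free_names, best.x))
    values.update(fixed_vals)
    resid = best.fun
    n, p_free = len(q), len(free)
    dof = max(n - p_free, 1)
    chi2_red = float(np.sum(resid**2) / dof)
    converged = bool(best.status > 0)

    # covariance of the linearized problem, scaled by reduced chi-square
    jac = best.jac
    jtj = jac.T @ jac
    stderr = {}
    try:
        u, sv, vt = np.linalg.svd(jtj)
        tol = sv.max() * max(jtj.shape) * np.finfo(float).eps if sv.size else 0.0
        inv_sv = np.where(sv > tol, 1.0 / np.maximum(sv, 1e-300), np.nan)
        cov = (vt.T * inv_sv) @ vt * chi2_red
        diag = np.diag(cov)
        for name, var in zip(free_names, diag):
            stderr[name] = float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else float("nan")
        cov_full = cov
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        cov_full = np.full((p_free, p_free), np.nan)
        stderr = {name: float("nan") for name in free_names}
    return values, stderr, chi2_red, resid, converged, cov_full, free_names


def _window_of(profile: ScatteringProfile) -> tuple[float, float]:
    return (float(profile.q[0]), float(profile.q[-1]))


# ---------------------------------------------------------------------------
# public fitting operations

def fit_composite(
    profile: ScatteringProfile,
    init: CompositeModel,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    fixed: Iterable[str] | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit a composite GGP (+ Porod shoulder, + background) model.

    ``fixed`` names parameters held at their init values (public names:
    i0_j, rg_j, s_j, d_j per component j, D_s, ds, background; fixing d_j
    holds the offset d - s).  ``bounds`` overrides :data:`DEFAULT_BOUNDS`
    per public name.  Non-convergence is reported via
    ``FitResult.converged``, not raised.
    """
    params = _composite_params(init, bounds, fixed)

    def predict(values: Mapping[str, float], q: np.ndarray) -> np.ndarray:
        return composite_intensity(_build_composite(init, values), q)

    values, stderr_raw, chi2_red, resid, converged, cov, free_names = _run_fit(
        profile, params, predict, n_starts, seed, _window_of(profile)
    )
    fitted = _build_composite(init, values)

    # translate (s, delta) -> (s, d) with covariance propagation for d,
    # then relabel components by descending rg (subscript 1 = large)
    n_comp = len(init.ggp_components)
    order = sorted(range(n_comp), key=lambda j: -fitted.ggp_components[j].rg)
    estimates: dict[str, float] = {}
    stderr: dict[str, float] = {}

    def d_stderr(j: int) -> float:
        s_name, dl_name = f"s_{j}", f"delta_{j}"
        in_free = {n: i for i, n in enumerate(free_names)}
        if dl_name not in in_free:
            return float("nan")  # d fixed -> no stderr entry (handled by caller)
        var = cov[in_free[dl_name], in_free[dl_name]]
        if s_name in in_free:
            var = (
                var
                + cov[in_free[s_name], in_free[s_name]]
                + 2.0 * cov[in_free[s_name], in_free[dl_name]]
            )
        return float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else float("nan")

    for new_j, old_j in enumerate(order, start=1):
        comp = fitted.ggp_components[old_j]
        estimates[f"i0_{new_j}"] = comp.i0
        estimates[f"rg_{new_j}"] = comp.rg
        estimates[f"d_{new_j}"] = comp.d
        estimates[f"s_{new_j}"] = comp.s
        for kind in ("i0", "rg", "s"):
            raw = f"{kind}_{old_j + 1}"
            if raw in stderr_raw:
                stderr[f"{kind}_{new_j}"] = stderr_raw[raw]
        if f"delta_{old_j + 1}" in stderr_raw:
            stderr[f"d_{new_j}"] = d_stderr(old_j + 1)
    for name in ("D_s", "ds", "background"):
        if name in values:
            estimates[name] = values[name]
            if name in stderr_raw:
                stderr[name] = stderr_raw[name]

    return FitResult(
        model=fitted.sorted_by_rg(),
        estimates=estimates,
        stderr=stderr,
        chi2_reduced=chi2_red,
        residuals=resid,
        n_free=len(free_names),
        converged=converged,
        fit_window=_window_of(profile),
        extras={"n_starts": n_starts, "seed": seed},
    )


def _linearized_db(profile: ScatteringProfile) -> dict[str, float]:
    """Debye-Bueche linearization: I^(-1/2) is linear in q^2 with intercept
    1/sqrt(A) and slope xi^2/sqrt(A)."""
    mask = profile.intensity > 0
    x = profile.q[mask] ** 2
    y = profile.intensity[mask] ** -0.5
    if x.size < 2:
        return {"amplitude": float("nan"), "xi": float("nan")}
    slope, intercept = np.polyfit(x, y, 1)
    if intercept <= 0 or slope <= 0:
        return {"amplitude": float("nan"), "xi": float("nan")}
    return {"amplitude": float(intercept**-2), "xi": float(math.sqrt(slope / intercept))}


def fit_debye_bueche(
    profile: ScatteringProfile,
    window: tuple[float, float] | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Fit I = A/(1 + xi^2 q^2)^2 on an optional q window.

    The closed-form linearized estimate (I^(-1/2) vs q^2 regression) is
    reported in ``extras["linearized"]`` as an independent diagnostic and
    used to seed the nonlinear fit.
    """
    data = restrict_q(profile, *window) if window is not None else profile
    if len(data) < 5:
        raise InsufficientDataError("Debye-Bueche fit needs at least 5 points")
    lin = _linearized_db(data)
    a0 = lin["amplitude"] if np.isfinite(lin["amplitude"]) else float(np.max(data.intensity))
    xi0 = lin["xi"] if np.isfinite(lin["xi"]) else 1.0 / float(np.median(data.q))
    params = [
        _Param("A", a0, 1e-12, np.inf),
        _Param("xi", xi0, 1e-3, 1e3),
    ]

    def predict(values: Mapping[str, float], q: np.ndarray) -> np.ndarray:
        return values["A"] / (1.0 + values["xi"] ** 2 * q**2) ** 2

    values, stderr, chi2_red, resid, converged, _, free_names = _run_fit(
        data, params, predict, n_starts, seed, _window_of(data)
    )
    model = DebyeBuecheParams(amplitude=values["A"], xi=values["xi"])
    return FitResult(
        model=model,
        estimates=dict(values),
        stderr=stderr,
        chi2_reduced=chi2_red,
        residuals=resid,
        n_free=len(free_names),
        converged=converged,
        fit_window=_window_of(data),
        extras={"linearized": lin},
    )


def fit_db_plus_oz(
    profile: ScatteringProfile,
    window: tuple[float, float] | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Fit the 4-parameter Debye-Bueche + Ornstein-Zernike sum.

    The Ornstein-Zernike amplitude is allowed to reach zero so that data
    generated by Debye-Bueche alone yield an estimate consistent with zero;
    in that case the fitted model's ``oz`` term is None.
    """
    data = restrict_q(profile, *window) if window is not None else profile
    if len(data) < 5:
        raise InsufficientDataError("DB+OZ fit needs at least 5 points")
    lin = _linearized_db(data)
    a0 = lin["amplitude"] if np.isfinite(lin["amplitude"]) else float(np.max(data.intensity))
    xi0 = lin["xi"] if np.isfinite(lin["xi"]) else 1.0 / float(np.median(data.q))
    params = [
        _Param("A_db", a0, 1e-12, np.inf),
        _Param("xi_db", xi0, 1e-3, 1e3),
        _Param("A_oz", 0.1 * a0, 0.0, np.inf),
        _Param("xi_oz", max(xi0 / 3.0, 2e-3), 1e-3, 1e3),
    ]

    def predict(values: Mapping[str, float], q: np.ndarray) -> np.ndarray:
        db = values["A_db"] / (1.0 + values["xi_db"] ** 2 * q**2) ** 2
        oz = values["A_oz"] / (1.0 + values["xi_oz"] ** 2 * q**2)
        return db + oz

    values, stderr, chi2_red, resid, converged, _, free_names = _run_fit(
        data, params, predict, n_starts, seed, _window_of(data)
    )
    db = DebyeBuecheParams(amplitude=values["A_db"], xi=values["xi_db"])
    oz = (
        OrnsteinZernikeParams(amplitude=values["A_oz"], xi=values["xi_oz"])
        if values["A_oz"] > 0
        else None
    )
    return FitResult(
        model=GelModel(db=db, oz=oz),
        estimates=dict(values),
        stderr=stderr,
        chi2_reduced=chi2_red,
        residuals=resid,
        n_free=len(free_names),
        converged=converged,
        fit_window=_window_of(data),
        extras={"linearized": lin},
    )


def compare_models(
    fits: Sequence[FitResult], improvement_threshold: float = 0.05
) -> ModelComparison:
    """Rank fits of the same data by reduced chi-square and select with a
    parsimony rule: a more complex model is adopted only if it improves the
    reduced chi-square by more than ``improvement_threshold`` (fractional).

    Ties in chi-square rank the model with fewer free parameters first.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("compare_models needs at least one fit")
    windows = {f.fit_window for f in fits}
    sizes = {len(f.residuals) for f in fits}
    if len(windows) > 1 or len(sizes) > 1:
        raise ValueError("all fits must share the same data and q window")

    ranked = sorted(fits, key=lambda f: (f.chi2_reduced, f.n_free))
    notes: list[str] = []
    by_complexity = sorted(fits, key=lambda f: f.n_free)
    selected = by_complexity[0]
    for cand in by_complexity[1:]:
        if cand.chi2_reduced < (1.0 - improvement_threshold) * selected.chi2_reduced:
            selected = cand
        else:
            notes.append(
                f"model with {cand.n_free} free parameters not required "
                f"(reduced chi2 {cand.chi2_reduced:.4g} vs {selected.chi2_reduced:.4g})"
            )
    return ModelComparison(ranked=ranked, selected=selected, notes=notes)
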