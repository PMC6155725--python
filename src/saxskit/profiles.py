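"""1-D scattering profile container, I/O, and pre-processing.

Profiles are plain-text columnar files (the de-facto ".dat" convention):
whitespace- or comma-delimited numeric columns q, I [, sigma], with
'#'-prefixed comment lines.  The canonical q unit throughout the package is
nm^-1; an explicit converter from Angstrom^-1 is provided because most
public SAXS data use that unit.

Pre-processing operations: background subtraction (uncertainties combined
in quadrature, negative results retained), replicate averaging, q-window
restriction, and the Kratky transformation q^2 I(q).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import (
    EmptyWindowError,
    GridMismatchError,
    InsufficientDataError,
    ProfileFormatError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScatteringProfile",
    "KratkyProfile",
    "read_profile",
    "write_profile",
    "write_kratky",
    "subtract_background",
    "average_profiles",
    "kratky_transform",
    "restrict_q",
    "q_angstrom_to_nm",
]

_GRID_RTOL = 1e-9


@dataclass(frozen=True)
class ScatteringProfile:
    """A measured or simulated 1-D scattering curve.

    Attributes
    ----------
    q : momentum transfer grid, nm^-1; strictly increasing, all > 0.
    intensity : scattered intensity, arbitrary units; same length as q.
    sigma : optional per-point intensity uncertainties (> 0), same units.
    label : free-text sample identifier.
    concentration : optional cellulose mole fraction, mol %
        (glucose unit / (glucose unit + ionic-liquid ion pair)).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    concentration: float | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", intensity)
        if q.ndim != 1 or q.size == 0:
            raise ValueError("q must be a non-empty 1-D array")
        if np.any(q <= 0):
            raise ValueError("all q values must be positive")
        if q.size > 1 and np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing")
        if intensity.shape != q.shape:
            raise ValueError("intensity must have the same length as q")
        if self.sigma is not None:
            sigma = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", sigma)
            if sigma.shape != q.shape:
                raise ValueError("sigma must have the same length as q")
            if np.any(sigma <= 0):
                raise ValueError("all sigma values must be positive")

    def __len__(self) -> int:
        return int(self.q.size)


@dataclass(frozen=True)
class KratkyProfile:
    """The Kratky representation q^2 I(q) of a profile."""

    q: np.ndarray
    kratky: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        kratky = np.asarray(self.kratky, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "kratky", kratky)
        if q.shape != kratky.shape:
            raise ValueError("kratky must have the same length as q")

    def __len__(self) -> int:
        return int(self.q.size)


def _parse_row(line: str) -> list[float]:
    return [float(tok) for tok in line.replace(",", " ").split()]


def read_profile(
    path: str | Path,
    dialect: str = "auto",
    label: str | None = None,
    concentration: float | None = None,
) -> ScatteringProfile:
    """Read a columnar text profile.

    ``dialect`` is one of ``two_column`` (q, I), ``three_column``
    (q, I, sigma) or ``auto`` (use sigma when a third column is present).
    Lines starting with '#' and blank lines are skipped.  Rows with
    non-positive q are dropped with a logged warning; a descending q column
    is sorted ascending with a logged notice.
    """
    if dialect not in ("two_column", "three_column", "auto"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                vals = _parse_row(line)
            except ValueError:
                raise ProfileFormatError(
                    f"{path}: unparseable line {lineno}: {line!r}"
                ) from None
            if len(vals) < 2:
                raise ProfileFormatError(
                    f"{path}: line {lineno} has fewer than 2 columns: {line!r}"
                )
            rows.append(vals)
    if not rows:
        raise InsufficientDataError(f"{path}: no data rows")

    n_cols = min(len(r) for r in rows)
    want_sigma = (dialect == "three_column") or (dialect == "auto" and n_cols >= 3)
    if dialect == "three_column" and n_cols < 3:
        raise ProfileFormatError(f"{path}: three_column dialect but only {n_cols} columns")

    data = np.array([r[: 3 if want_sigma else 2] for r in rows], dtype=float)
    q, intensity = data[:, 0], data[:, 1]
    sigma = data[:, 2] if want_sigma else None

    bad = q <= 0
    if bad.any():
        logger.warning("%s: dropped %d rows with non-positive q", path, int(bad.sum()))
        q, intensity = q[~bad], intensity[~bad]
        if sigma is not None:
            sigma = sigma[~bad]
    if q.size < 2:
        raise InsufficientDataError(f"{path}: fewer than 2 usable rows")
    order = np.argsort(q, kind="stable")
    if not np.array_equal(order, np.arange(q.size)):
        logger.info("%s: q column not ascending; sorted", path)
        q, intensity = q[order], intensity[order]
        if sigma is not None:
            sigma = sigma[order]
    return ScatteringProfile(
        q=q,
        intensity=intensity,
        sigma=sigma,
        label=path.stem if label is None else label,
        concentration=concentration,
    )


def write_profile(
    profile: ScatteringProfile, path: str | Path, header_lines: Sequence[str] = ()
) -> Path:
    """Write a profile in the columnar text format read_profile accepts."""
    path = Path(path)
    with path.open("w") as fh:
        if profile.label:
            fh.write(f"# label: {profile.label}\n")
        if profile.concentration is not None:
            fh.write(f"# concentration_mol_pct: {profile.concentration:g}\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        cols = "q_nm^-1 I_au" + (" sigma_au" if profile.sigma is not None else "")
        fh.write(f"# columns: {cols}\n")
        for i in range(len(profile)):
            if profile.sigma is not None:
                fh.write(
                    f"{profile.q[i]:.9e} {profile.intensity[i]:.9e} {profile.sigma[i]:.9e}\n"
                )
            else:
                fh.write(f"{profile.q[i]:.9e} {profile.intensity[i]:.9e}\n")
    return path


def write_kratky(kratky: KratkyProfile, path: str | Path, header_lines: Sequence[str] = ()) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# columns: q_nm^-1 q2I_nm^-2au\n")
        for qi, ki in zip(kratky.q, kratky.kratky):
            fh.write(f"{qi:.9e} {ki:.9e}\n")
    return path


def q_angstrom_to_nm(profile: ScatteringProfile) -> ScatteringProfile:
    """Convert a profile whose q grid is in Angstrom^-1 to nm^-1 (q x 10)."""
    return replace(profile, q=profile.q * 10.0)


def _grids_match(a: np.ndarray, b: np.ndarray) -> bool:
    return a.shape == b.shape and np.allclose(a, b, rtol=_GRID_RTOL, atol=0.0)


def subtract_background(
    sample: ScatteringProfile,
    background: ScatteringProfile,
    scale: float = 1.0,
    interpolate: bool = False,
) -> ScatteringProfile:
    """Subtract ``scale x background`` from ``sample``.

    Grids must match to 1e-9 relative tolerance unless ``interpolate`` is
    set, in which case the background is linearly interpolated onto the
    sample grid.  Uncertainties, when both present, combine in quadrature.
    Negative resulting intensities are retained (clipping would bias a
    weighted fit) and their count is logged.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    if _grids_match(sample.q, background.q):
        bg_i = background.intensity
        bg_s = background.sigma
    elif interpolate:
        bg_i = np.interp(sample.q, background.q, background.intensity)
        bg_s = (
            np.interp(sample.q, background.q, background.sigma)
            if background.sigma is not None
            else None
        )
    else:
        raise GridMismatchError(
            "sample and background q grids differ; pass interpolate=True to resample"
        )
    intensity = sample.intensity - scale * bg_i
    n_neg = int((intensity < 0).sum())
    if n_neg:
        logger.info("background subtraction left %d negative intensities", n_neg)
    sigma = None
    if sample.sigma is not None and bg_s is not None:
        sigma = np.sqrt(sample.sigma**2 + (scale * bg_s) ** 2)
    elif sample.sigma is not None:
        sigma = sample.sigma.copy()
    return replace(sample, intensity=intensity, sigma=sigma)


def average_profiles(profiles: Sequence[ScatteringProfile]) -> ScatteringProfile:
    """Pointwise mean of replicate profiles sharing one q grid.

    The uncertainty of the mean is the sample standard deviation / sqrt(n)
    when n >= 2 and the inputs carry no sigmas; otherwise it is propagated
    from the input sigmas as sqrt(sum sigma_i^2)/n.
    """
    profiles = list(profiles)
    if not profiles:
        raise InsufficientDataError("average_profiles requires at least one profile")
    ref = profiles[0]
    for p in profiles[1:]:
        if not _grids_match(ref.q, p.q):
            raise GridMismatchError("replicate q grids differ")
    n = len(profiles)
    stack = np.stack([p.intensity for p in profiles])
    mean = stack.mean(axis=0)
    have_sigmas = all(p.sigma is not None for p in profiles)
    if have_sigmas:
        sig_stack = np.stack([p.sigma for p in profiles])
        sigma = np.sqrt((sig_stack**2).sum(axis=0)) / n
    elif n >= 2:
        sigma_vals = stack.std(axis=0, ddof=1) / np.sqrt(n)
        if np.all(sigma_vals > 0):
            sigma = sigma_vals
        elif np.any(sigma_vals > 0):
            # isolated exactly-equal points: floor at the smallest positive sd
            # so the container's sigma > 0 invariant holds
            sigma = np.clip(sigma_vals, sigma_vals[sigma_vals > 0].min(), None)
        else:
            # identical replicates: zero spread, report no uncertainty
            sigma = None
    else:
        sigma = None
    return replace(ref, intensity=mean, sigma=sigma)


def kratky_transform(profile: ScatteringProfile) -> KratkyProfile:
    """Return q^2 I(q) on the profile's own grid."""
    return KratkyProfile(q=profile.q.copy(), kratky=profile.q**2 * profile.intensity)


def restrict_q(
    profile: ScatteringProfile, qmin: float, qmax: float
) -> ScatteringProfile:
    """Subset the profile to qmin <= q <= qmax, preserving metadata."""
    if not qmin < qmax:
        raise ValueError(f"qmin must be < qmax, got [{qmin}, {qmax}]")
    mask = (profile.q >= qmin) & (profile.q <= qmax)
    if not mask.any():
        raise EmptyWindowError(
            f"window [{qmin}, {qmax}] contains no points of the profile"
        )
    sigma = profile.sigma[mask] if profile.sigma is not None else None
    return replace(
        profile, q=profile.q[mask], intensity=profile.intensity[mask], sigma=sigma
    )
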