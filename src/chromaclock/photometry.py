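"""Opsin photometry and silent-substitution stimulus design.

This module computes opsin-weighted effective photon fluxes from spectral
power distributions and solves for multi-primary *metamers*: spectrally
distinct lights that hold the excitation of designated photoreceptor classes
(here typically melanopsin and rods) fixed while pushing the cone-opponent
color axis (L vs S excitation) as far as the primaries' drive range allows.

Spectral sensitivities follow the Govardovskii et al. (2000) A1 visual
pigment template, optionally corrected for pre-receptoral lens transmission.
All fluxes are photon fluxes (photons/cm^2/s), integrated by the trapezoidal
rule on a common wavelength grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import brentq

__all__ = [
    "DEFAULT_GRID",
    "OpsinTemplate",
    "LensTransmission",
    "SpectralPowerDistribution",
    "ReceptorFluxes",
    "PrimaryBasis",
    "StimulusDesign",
    "MOUSE_LAMBDA_MAX",
    "build_opsin_template",
    "apply_lens",
    "effective_flux",
    "receptor_fluxes",
    "color_coordinate",
    "mu_LS",
    "gaussian_primary",
    "solve_metamer",
    "design_metamer_pair",
    "scale_to_flux",
    "mouse_photoreceptors",
]

#: Default 1-nm wavelength grid covering the full template support, in nm.
DEFAULT_GRID = np.arange(300.0, 781.0, 1.0)

#: Peak sensitivities (nm) of the photopigments of the red-cone mouse:
#: UV-sensitive S-cone opsin, human L-cone opsin (replacing the native
#: M-opsin in the Opn1mw^R line), melanopsin, and rod opsin.
MOUSE_LAMBDA_MAX = {"S": 365.0, "L": 556.0, "mel": 480.0, "rod": 498.0}


class InfeasibleDesignError(ValueError):
    """Raised when no weight vector within drive bounds meets the constraints."""


# ---------------------------------------------------------------------------
# Pigment templates and lens transmission
# ---------------------------------------------------------------------------


def _govardovskii_alpha_band(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    # A1 alpha-band template constants (Govardovskii et al. 2000, Vis Neurosci).
    x = lambda_max / wavelengths
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    with np.errstate(over="ignore"):
        s = 1.0 / (
            np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D
        )
    return s


def _govardovskii_beta_band(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    lambda_max_beta = 189.0 + 0.315 * lambda_max
    bandwidth = -40.5 + 0.195 * lambda_max
    return 0.26 * np.exp(-(((wavelengths - lambda_max_beta) / bandwidth) ** 2))


@dataclass(frozen=True)
class OpsinTemplate:
    """Normalized spectral sensitivity of one photopigment class.

    Attributes
    ----------
    name : str
        Label for the photoreceptor class (e.g. ``"mel"``).
    lambda_max : float
        Peak wavelength of the alpha band, nm.
    wavelengths : ndarray
        Wavelength grid, nm, ascending.
    sensitivity : ndarray
        Normalized sensitivity (peak = 1) on ``wavelengths``.
    family : str
        Pigment template family; only the vitamin-A1 family is provided.
    include_beta_band : bool
        Whether the UV beta band is included.
    """

    name: str
    lambda_max: float
    wavelengths: np.ndarray
    sensitivity: np.ndarray
    family: str = "A1"
    include_beta_band: bool = True

    def __call__(self, wavelength: float | np.ndarray) -> float | np.ndarray:
        """Interpolate the normalized sensitivity at ``wavelength`` (nm)."""
        return np.interp(wavelength, self.wavelengths, self.sensitivity)


def build_opsin_template(
    lambda_max: float,
    include_beta_band: bool = True,
    grid: np.ndarray | None = None,
    name: str | None = None,
) -> OpsinTemplate:
    """Build a Govardovskii A1 pigment template normalized to peak 1.

    Parameters
    ----------
    lambda_max : float
        Alpha-band peak, nm. Must lie in the template's published validity
        range, 330-600 nm.
    include_beta_band : bool
        Add the UV beta band. On by default: for long-wavelength pigments the
        beta band contributes non-negligibly in the near-UV region where the
        mouse S-opsin (365 nm) stimuli live.
    grid : ndarray, optional
        Wavelength grid in nm; defaults to a 1-nm grid on [300, 780].
    name : str, optional
        Label; defaults to ``"opsin<lambda_max>"``.
    """
    if not (330.0 <= lambda_max <= 600.0):
        raise ValueError(
            f"lambda_max={lambda_max} nm outside the A1 template validity "
            "range [330, 600] nm"
        )
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid[0] > 300.0 or grid[-1] < 780.0:
        raise ValueError("grid must cover [300, 780] nm")
    s = _govardovskii_alpha_band(grid, lambda_max)
    if include_beta_band:
        s = s + _govardovskii_beta_band(grid, lambda_max)
    s = s / s.max()
    return OpsinTemplate(
        name=name or f"opsin{lambda_max:g}",
        lambda_max=lambda_max,
        wavelengths=grid,
        sensitivity=s,
        include_beta_band=include_beta_band,
    )


@dataclass(frozen=True)
class LensTransmission:
    """Fraction of light transmitted by the lens, per wavelength."""

    wavelengths: np.ndarray
    fraction: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.fraction, dtype=float)
        if np.any(f < 0.0) or np.any(f > 1.0):
            raise ValueError("lens transmission must lie in [0, 1]")

    @classmethod
    def identity(cls, grid: np.ndarray | None = None) -> "LensTransmission":
        """Fully transparent lens (useful for tests)."""
        grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
        return cls(grid, np.ones_like(grid))

    @classmethod
    def mouse_default(cls, grid: np.ndarray | None = None) -> "LensTransmission":
        """Smooth approximation to mouse lens transmission.

        The mouse lens transmits substantial near-UV light (unlike the human
        lens), with transmission falling off smoothly below ~400 nm. This
        default is a logistic curve with midpoint 345 nm reaching a 25%
        short-wavelength floor; it is a documented approximation, and every
        numerical contract in this module holds for any transmission curve.
        """
        grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
        frac = 0.25 + 0.75 / (1.0 + np.exp(-(grid - 345.0) / 20.0))
        return cls(grid, np.clip(frac, 0.0, 1.0))


def apply_lens(template: OpsinTemplate, lens: LensTransmission) -> OpsinTemplate:
    """Correct a pigment template for lens transmission.

    The corrected sensitivity is the pointwise product of template and
    transmitted fraction, re-normalized to peak 1.
    """
    if (
        lens.wavelengths[0] > template.wavelengths[0]
        or lens.wavelengths[-1] < template.wavelengths[-1]
    ):
        raise ValueError("lens grid does not cover the template support")
    frac = np.interp(template.wavelengths, lens.wavelengths, lens.fraction)
    s = template.sensitivity * frac
    peak = s.max()
    if peak <= 0.0:
        raise ValueError("lens transmission annihilates the template")
    return replace(template, sensitivity=s / peak)


# ---------------------------------------------------------------------------
# Spectra and fluxes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectralPowerDistribution:
    """A light spectrum as photon flux density per wavelength.

    Attributes
    ----------
    wavelengths : ndarray
        Ascending, uniformly spaced grid, nm.
    flux_density : ndarray
        Photon flux density, photons/cm^2/s/nm, non-negative.
    """

    wavelengths: np.ndarray
    flux_density: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        fd = np.asarray(self.flux_density, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or fd.shape != wl.shape:
            raise ValueError("wavelengths and flux_density must be matching 1-D arrays")
        steps = np.diff(wl)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
            raise ValueError("wavelength grid must be ascending with uniform step")
        if np.any(fd < 0):
            raise ValueError("flux density must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "flux_density", fd)

    def scaled(self, factor: float) -> "SpectralPowerDistribution":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return SpectralPowerDistribution(self.wavelengths, self.flux_density * factor)

    def total_flux(self) -> float:
        """Total photon flux (photons/cm^2/s), trapezoidal integral."""
        return float(np.trapezoid(self.flux_density, self.wavelengths))


def gaussian_primary(
    peak: float,
    fwhm: float = 20.0,
    total_flux: float = 1.0,
    grid: np.ndarray | None = None,
) -> SpectralPowerDistribution:
    """Synthetic Gaussian LED primary integrating to ``total_flux``."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    profile = np.exp(-0.5 * ((grid - peak) / sigma) ** 2)
    integral = np.trapezoid(profile, grid)
    return SpectralPowerDistribution(grid, profile * (total_flux / integral))


def effective_flux(spd: SpectralPowerDistribution, template: OpsinTemplate) -> float:
    """Effective photon flux for one opsin: integral of SPD x sensitivity.

    Linear and homogeneous in the SPD; trapezoidal quadrature on the shared
    wavelength grid.
    """
    if spd.wavelengths.shape != template.wavelengths.shape or not np.allclose(
        spd.wavelengths, template.wavelengths
    ):
        raise ValueError("SPD and template must share a wavelength grid")
    return float(np.trapezoid(spd.flux_density * template.sensitivity, spd.wavelengths))


@dataclass(frozen=True)
class ReceptorFluxes:
    """Per-opsin effective photon fluxes, linear and log10.

    ``log10`` holds NaN (with the receptor listed in ``undefined``) wherever
    the linear flux is zero, so darkness never silently propagates -inf.
    """

    flux: dict[str, float]

    @property
    def log10(self) -> dict[str, float]:
        out = {}
        for k, v in self.flux.items():
            out[k] = float(np.log10(v)) if v > 0 else float("nan")
        return out

    @property
    def undefined(self) -> list[str]:
        return [k for k, v in self.flux.items() if v <= 0]

    def __getitem__(self, key: str) -> float:
        return self.flux[key]


def mouse_photoreceptors(
    grid: np.ndarray | None = None,
    lens: LensTransmission | None = None,
    lambda_max: dict[str, float] | None = None,
    include_beta_band: bool = True,
) -> dict[str, OpsinTemplate]:
    """Lens-corrected templates for the standard red-cone mouse opsin set.

    Returns a dict mapping ``{"S", "L", "mel", "rod"}`` to corrected
    templates. Pass ``lens=LensTransmission.identity()`` to disable the lens
    correction; pass ``lambda_max={"L": 511.0, ...}`` to model e.g. the native
    M-opsin instead of the knocked-in human L-opsin.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    lens = LensTransmission.mouse_default(grid) if lens is None else lens
    peaks = dict(MOUSE_LAMBDA_MAX)
    if lambda_max:
        peaks.update(lambda_max)
    return {
        name: apply_lens(
            build_opsin_template(lm, include_beta_band, grid, name=name), lens
        )
        for name, lm in peaks.items()
    }


def receptor_fluxes(
    spd: SpectralPowerDistribution, photoreceptors: dict[str, OpsinTemplate]
) -> ReceptorFluxes:
    """Effective photon flux for every opsin class in ``photoreceptors``."""
    return ReceptorFluxes(
        {name: effective_flux(spd, t) for name, t in photoreceptors.items()}
    )


def color_coordinate(
    fluxes: ReceptorFluxes, white_point: ReceptorFluxes | None = None
) -> float:
    """Cone-opponent color coordinate: log10(L) - log10(S), white-referenced.

    Positive values are yellow-shifted (L-biased) relative to the white
    point, negative values blue-shifted (S-biased). With no white point the
    raw log ratio is returned.
    """
    c = np.log10(fluxes["L"]) - np.log10(fluxes["S"])
    if white_point is not None:
        c -= np.log10(white_point["L"]) - np.log10(white_point["S"])
    return float(c)


def mu_LS(fluxes: ReceptorFluxes) -> float:
    """Mean cone log-illuminance: arithmetic mean of log10 L and log10 S flux."""
    return float(0.5 * (np.log10(fluxes["L"]) + np.log10(fluxes["S"])))


# ---------------------------------------------------------------------------
# Metamer design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimaryBasis:
    """A set of independently drivable light primaries on a common grid.

    Each primary is its spectrum at unit drive; drives are bounded in
    ``[lower, upper]`` (default [0, 1]) per primary.
    """

    primaries: tuple[SpectralPowerDistribution, ...]
    labels: tuple[str, ...] = ()
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self):
        prim = tuple(self.primaries)
        if len(prim) < 2:
            raise ValueError("a basis needs at least 2 primaries")
        grid = prim[0].wavelengths
        for p in prim[1:]:
            if not np.array_equal(p.wavelengths, grid):
                raise ValueError("all primaries must share a wavelength grid")
        labels = tuple(self.labels) or tuple(f"p{i}" for i in range(len(prim)))
        if len(labels) != len(prim):
            raise ValueError("one label per primary required")
        object.__setattr__(self, "primaries", prim)
        object.__setattr__(self, "labels", labels)

    @property
    def n_primaries(self) -> int:
        return len(self.primaries)

    def flux_matrix(self, photoreceptors: dict[str, OpsinTemplate]) -> tuple[np.ndarray, list[str]]:
        """Matrix M[r, p] of effective flux of primary p for receptor r."""
        names = list(photoreceptors)
        M = np.array(
            [
                [effective_flux(p, photoreceptors[r]) for p in self.primaries]
                for r in names
            ]
        )
        return M, names

    def mix(self, weights: np.ndarray) -> SpectralPowerDistribution:
        """Spectrum of the basis driven at ``weights``."""
        w = np.asarray(weights, dtype=float)
        fd = sum(wi * p.flux_density for wi, p in zip(w, self.primaries))
        return SpectralPowerDistribution(self.primaries[0].wavelengths, fd)


@dataclass(frozen=True)
class StimulusDesign:
    """A solved stimulus: drive weights plus an audit of what they achieve."""

    basis: PrimaryBasis
    weights: np.ndarray
    fluxes: ReceptorFluxes
    color: float
    mu_LS: float
    white_point: ReceptorFluxes | None = None

    def audit(self) -> dict:
        """JSON-ready audit block: weights, per-opsin log fluxes, color, mu."""
        return {
            "weights": {l: float(w) for l, w in zip(self.basis.labels, self.weights)},
            "log10_flux": {k: v for k, v in self.fluxes.log10.items()},
            "color": self.color,
            "mu_LS": self.mu_LS,
        }


def _design_from_weights(
    basis: PrimaryBasis,
    weights: np.ndarray,
    photoreceptors: dict[str, OpsinTemplate],
    white_point: ReceptorFluxes | None,
) -> StimulusDesign:
    fl = receptor_fluxes(basis.mix(weights), photoreceptors)
    return StimulusDesign(
        basis=basis,
        weights=np.asarray(weights, dtype=float),
        fluxes=fl,
        color=color_coordinate(fl, white_point),
        mu_LS=mu_LS(fl),
        white_point=white_point,
    )


def _feasible_interval(w0: np.ndarray, v: np.ndarray, lo: float, hi: float):
    """Range of t keeping w0 + t*v inside [lo, hi] elementwise."""
    t_lo, t_hi = -np.inf, np.inf
    for w0i, vi in zip(w0, v):
        if abs(vi) < 1e-15:
            if not (lo - 1e-12 <= w0i <= hi + 1e-12):
                return None
            continue
        a, b = (lo - w0i) / vi, (hi - w0i) / vi
        if a > b:
            a, b = b, a
        t_lo, t_hi = max(t_lo, a), min(t_hi, b)
    if t_lo > t_hi:
        return None
    return t_lo, t_hi


def solve_metamer(
    basis: PrimaryBasis,
    photoreceptors: dict[str, OpsinTemplate],
    equality_targets: dict[str, float],
    contrast_axis: tuple[str, str] = ("L", "S"),
    direction: int = +1,
    white_point: ReceptorFluxes | None = None,
    null_offset: float | None = None,
) -> StimulusDesign:
    """Solve for drive weights that pin some receptors and push a color axis.

    The equality constraints (``equality_targets``: receptor name ->
    target log10 photon flux) are solved exactly in linear-flux space; the
    remaining degrees of freedom (the constraint null space) are then pushed
    in the ``direction``-signed sense of the contrast
    ``log10(flux[axis0]) - log10(flux[axis1])`` until a drive bound is hit.

    With 3 primaries and melanopsin+rod targets this reproduces the classic
    silent-substitution construction: blue (direction=-1) and yellow
    (direction=+1) end-points that are metameric for melanopsin and rods.

    Parameters
    ----------
    null_offset : float, optional
        Stop short of the bound at this signed null-space coordinate instead
        of at the extreme (used internally to equalize mu(L,S) in pairs).

    Raises
    ------
    InfeasibleDesignError
        If no non-negative in-bounds weight vector satisfies the targets.
    """
    M, names = basis.flux_matrix(photoreceptors)
    equality_targets = dict(equality_targets)
    mu_target = equality_targets.pop("mu", None)
    cons = list(equality_targets)
    missing = [r for r in cons if r not in names]
    if missing:
        raise ValueError(f"unknown receptors in equality targets: {missing}")
    E = np.array([M[names.index(r)] for r in cons])
    t = np.array([10.0 ** equality_targets[r] for r in cons])
    m = basis.n_primaries
    if m < len(cons):
        raise InfeasibleDesignError(
            f"{len(cons)} equality constraints need >= {len(cons)} primaries, got {m}"
        )

    # Minimum-norm particular solution + null space of the constraint matrix.
    w0, *_ = np.linalg.lstsq(E, t, rcond=None)
    if not np.allclose(E @ w0, t, rtol=1e-9, atol=1e-9 * max(t.max(), 1.0)):
        raise InfeasibleDesignError("equality targets are inconsistent for this basis")
    N = null_space(E)
    if N.shape[1] == 0:
        w = w0
        if np.any(w < basis.lower - 1e-12) or np.any(w > basis.upper + 1e-12):
            raise InfeasibleDesignError(
                f"unique solution violates drive bounds: weights={w}"
            )
        return _design_from_weights(basis, np.clip(w, basis.lower, basis.upper),
                                    photoreceptors, white_point)
    if N.shape[1] > 1:
        raise NotImplementedError(
            "null space dimension > 1: add equality targets (e.g. pin L and S) "
            "to reduce the free directions to at most one"
        )

    v = N[:, 0]
    iL, iS = names.index(contrast_axis[0]), names.index(contrast_axis[1])
    # Orient v so +t moves the contrast in the requested direction. The
    # contrast log10((a+bt)/(c+dt)) is monotone in t, so the optimum sits at
    # a feasible-interval endpoint.
    interval = _feasible_interval(w0, v, basis.lower, basis.upper)
    if interval is None:
        raise InfeasibleDesignError(
            "no weights within drive bounds satisfy the equality targets "
            f"(particular solution {w0})"
        )
    t_lo, t_hi = interval

    def contrast_at(tv: float) -> float:
        w = w0 + tv * v
        L = float(M[iL] @ w)
        S = float(M[iS] @ w)
        if L <= 0 or S <= 0:
            return -np.inf * direction
        return np.log10(L) - np.log10(S)

    c_lo, c_hi = contrast_at(t_lo), contrast_at(t_hi)
    # Deterministic tie-break: smallest-index bound (i.e. the lower-t
    # endpoint) when both ends achieve the same contrast.
    if direction >= 0:
        t_star = t_lo if c_lo >= c_hi else t_hi
    else:
        t_star = t_lo if c_lo <= c_hi else t_hi
    if mu_target is not None:
        # mu(L,S) is a nonlinear equality: locate it by root-finding along
        # the (1-D) null direction. This fully determines the stimulus, so
        # the contrast push does not apply.
        iLc, iSc = names.index("L"), names.index("S")

        def mu_err(tv: float) -> float:
            w = w0 + tv * v
            return 0.5 * (np.log10(M[iLc] @ w) + np.log10(M[iSc] @ w)) - mu_target

        e_lo, e_hi = mu_err(t_lo), mu_err(t_hi)
        if e_lo * e_hi > 0:
            raise InfeasibleDesignError(
                f"mu(L,S)={mu_target} unreachable within drive bounds "
                f"(attainable range [{min(e_lo, e_hi) + mu_target:.3f}, "
                f"{max(e_lo, e_hi) + mu_target:.3f}])"
            )
        t_star = brentq(mu_err, t_lo, t_hi, xtol=1e-13)
    if null_offset is not None:
        if not (t_lo - 1e-12 <= null_offset <= t_hi + 1e-12):
            raise InfeasibleDesignError("requested null offset outside bounds")
        t_star = null_offset

    w = np.clip(w0 + t_star * v, basis.lower, basis.upper)
    design = _design_from_weights(basis, w, photoreceptors, white_point)
    resid = max(
        abs(design.fluxes.log10[r] - equality_targets[r]) for r in cons
    )
    if resid > 1e-9:
        raise InfeasibleDesignError(
            f"constraint residual {resid:.2e} log units exceeds 1e-9"
        )
    return design


def design_metamer_pair(
    basis: PrimaryBasis,
    photoreceptors: dict[str, OpsinTemplate],
    equality_targets: dict[str, float],
    contrast_axis: tuple[str, str] = ("L", "S"),
    white_point: ReceptorFluxes | None = None,
) -> tuple[StimulusDesign, StimulusDesign]:
    """Design a (blue, yellow) metameric pair from one basis.

    Both stimuli satisfy the equality targets exactly; the blue member
    minimizes and the yellow member maximizes the L-S contrast within the
    drive bounds. With melanopsin and rod pinned this is the classic
    equi-luminant blue/yellow construction: the pair differs in color only,
    not in the circadian system's achromatic intensity estimate.

    Note that with three primaries the mean cone log-illuminance mu(L,S)
    varies monotonically along the single free color direction, so it
    cannot additionally be equalized between the endpoints; pass a
    ``"mu"`` equality target to :func:`solve_metamer` instead to obtain the
    single stimulus of a given cone illuminance (requires choosing one
    point, not a pair, per mu value — a fourth primary is needed to decouple
    mu from contrast).
    """
    blue = solve_metamer(basis, photoreceptors, equality_targets, contrast_axis,
                         direction=-1, white_point=white_point)
    yellow = solve_metamer(basis, photoreceptors, equality_targets, contrast_axis,
                           direction=+1, white_point=white_point)
    return blue, yellow


def scale_to_flux(
    design: StimulusDesign,
    photoreceptors: dict[str, OpsinTemplate],
    receptor: str,
    target_log10: float,
) -> StimulusDesign:
    """Uniformly rescale a design so one receptor hits a target log10 flux.

    Uniform scaling shifts every log flux by the same amount, so the color
    coordinate and any metameric equalities are preserved; this is the
    software analogue of slotting a neutral-density filter in front of the
    light source.
    """
    current = design.fluxes.log10[receptor]
    if not np.isfinite(current):
        raise ValueError(f"receptor {receptor!r} has zero flux; cannot scale")
    factor = 10.0 ** (target_log10 - current)
    new_w = design.weights * factor
    over = new_w > design.basis.upper + 1e-12
    under = new_w < design.basis.lower - 1e-12
    if over.any() or under.any():
        worst = np.argmax(new_w)
        headroom = (design.basis.upper / design.weights[worst]
                    if design.weights[worst] > 0 else np.inf)
        raise InfeasibleDesignError(
            f"scaling by {factor:.3g} pushes weights out of bounds; maximum "
            f"feasible uniform factor is {headroom:.3g} "
            f"({np.log10(headroom):+.3f} log units)"
        )
    return _design_from_weights(
        design.basis, new_w, photoreceptors, design.white_point
    )
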