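"""Analysis of polarized fluorescence and Raman images of GUV cross-sections.

The experimental route to the transition-dipole tilt: per-pixel anisotropy
maps from the two polarized channels, integration of the equatorial ring in
narrow angular sectors along and perpendicular to the excitation
polarization, and inversion of the photoselection sector ratio

    F_up-down / F_left-right = tan²(nu) / 2

to the tilt angle nu of the transition dipole against the membrane normal.
Also provides multi-exponential fluorescence-decay fitting, the confocal
volume of the ellipsoidal observation spot, and band-integration imaging of
hyperspectral Raman maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator

from .constants import DEFAULT_G_FACTOR
from .synthetic import GuvGeometry, GuvImagePair, RamanCube, _ring_fields

# ---------------------------------------------------------------------------
# Anisotropy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnisotropyObservation:
    """Parallel/perpendicular detected intensities with the G correction."""

    i_vv: float
    i_vh: float
    g: float = DEFAULT_G_FACTOR

    def __post_init__(self) -> None:
        if self.i_vv < 0 or self.i_vh < 0:
            raise ValueError("intensities must be nonnegative")
        if self.g <= 0:
            raise ValueError("G factor must be positive")


def anisotropy(obs=None, i_vv=None, i_vh=None, g: float = DEFAULT_G_FACTOR):
    """Fluorescence anisotropy ``r = (I_VV - G I_VH) / (I_VV + 2 G I_VH)``.

    Accepts either an :class:`AnisotropyObservation` or intensity scalars /
    arrays (per-pixel maps).  For arrays, pixels with zero denominator are
    returned as NaN (undefined-pixel marker) rather than raising.  Values
    outside the isotropic-solution range [-0.2, 0.4] are physically possible
    for oriented systems and are not rejected.
    """
    if obs is not None:
        i_vv, i_vh, g = obs.i_vv, obs.i_vh, obs.g
    i_vv = np.asarray(i_vv, dtype=float)
    i_vh = np.asarray(i_vh, dtype=float)
    den = i_vv + 2.0 * g * i_vh
    if i_vv.ndim == 0:
        if den == 0:
            raise ZeroDivisionError("anisotropy undefined: zero total intensity")
        return float((i_vv - g * i_vh) / den)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, (i_vv - g * i_vh) / den, np.nan)
    return r


# ---------------------------------------------------------------------------
# Ring localization and sector integration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectorIntensities:
    """Background-subtracted integrals of the ring in the two sector pairs.

    ``f_left_right`` covers the sectors along the excitation polarization
    axis, ``f_up_down`` the perpendicular pair; ``cone_half_angle`` is the
    angular half-width of each sector (deg).
    """

    f_up_down: float
    f_left_right: float
    cone_half_angle: float = 10.0
    background: float = 0.0
    n_pixels_up_down: int = 0
    n_pixels_left_right: int = 0
    # geometric second moments <cos²theta>, <sin²theta> over each sector mask,
    # used to invert the exact finite-sector photoselection relation
    moments: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.cone_half_angle < 45.0:
            raise ValueError("cone_half_angle must lie in (0, 45) degrees")

    @property
    def ratio(self) -> float:
        if self.f_left_right <= 0:
            return np.inf
        return self.f_up_down / self.f_left_right


def fit_ring(image: np.ndarray) -> tuple[tuple[float, float], float]:
    """Locate the GUV ring by intensity-weighted least squares.

    Thresholds the image (Otsu), takes the intensity-weighted centroid as
    the center and the intensity-weighted mean radial distance as the
    radius.  Returns ``((row, col), radius_px)``.
    """
    im = np.asarray(image, dtype=float)
    thr = threshold_otsu(im)
    w = np.clip(im - thr, 0.0, None)
    if w.sum() <= 0:
        raise ValueError("ring localization failed: no pixels above threshold")
    rows, cols = np.indices(im.shape)
    cy = float((rows * w).sum() / w.sum())
    cx = float((cols * w).sum() / w.sum())
    r = np.hypot(rows - cy, cols - cx)
    radius = float((r * w).sum() / w.sum())
    return (cy, cx), radius


def sector_integrate(
    image: np.ndarray,
    geometry: GuvGeometry,
    cone_half_angle: float = 10.0,
    annulus_sigmas: float = 2.0,
) -> SectorIntensities:
    """Integrate the ring within angular cones along and across the
    polarization axis.

    Pixels inside the radial annulus ``|r - R| <= annulus_sigmas *
    ring_sigma`` and within ``±cone_half_angle`` of the polarization axis
    (both sides) form the left–right sectors; the cones around the
    perpendicular axis form the up–down sectors.  The median intensity of
    pixels farther than 1.5 radii from the center is subtracted as
    background before summation.
    """
    im = np.asarray(image, dtype=float)
    r, ang = _ring_fields(im.shape, geometry.center, geometry.polarization_angle_deg)
    theta = np.degrees(ang)
    annulus = np.abs(r - geometry.radius_px) <= annulus_sigmas * geometry.ring_sigma_px
    exterior = r > 1.5 * geometry.radius_px
    background = float(np.median(im[exterior])) if exterior.any() else 0.0

    def cone_mask(center_deg: float) -> np.ndarray:
        d = np.abs((theta - center_deg + 180.0) % 360.0 - 180.0)
        return d <= cone_half_angle

    lr = annulus & (cone_mask(0.0) | cone_mask(180.0))
    ud = annulus & (cone_mask(90.0) | cone_mask(-90.0))
    if not lr.any() or not ud.any():
        raise ValueError("sector masks are empty; check geometry and cone angle")
    cos2 = np.cos(ang) ** 2
    moments = (
        float(cos2[ud].mean()),
        float(1.0 - cos2[ud].mean()),
        float(cos2[lr].mean()),
        float(1.0 - cos2[lr].mean()),
    )
    return SectorIntensities(
        f_up_down=float((im[ud] - background).sum()),
        f_left_right=float((im[lr] - background).sum()),
        cone_half_angle=cone_half_angle,
        background=background,
        n_pixels_up_down=int(ud.sum()),
        n_pixels_left_right=int(lr.sum()),
        moments=moments,
    )


def orientation_angle(sectors: SectorIntensities) -> float:
    """Transition-dipole tilt nu (deg) from the photoselection sector ratio.

    Inverts ``F_ud / F_lr = tan²(nu) / 2``:
    ``nu = arctan(sqrt(2 F_ud / F_lr))`` in [0°, 90°).  A vanishing
    left–right signal returns the 90° boundary.
    """
    if sectors.f_left_right <= 0:
        return 90.0
    ratio = max(sectors.f_up_down, 0.0) / sectors.f_left_right
    return float(np.degrees(np.arctan(np.sqrt(2.0 * ratio))))


def orientation_angle_finite_cone(sectors: SectorIntensities) -> float:
    """Tilt nu from the sector ratio, corrected for the finite sector width.

    With sectors of nonzero angular width, the expected sector integrals of
    the photoselection law are

        F ∝ cos²(nu) <cos²theta> + (sin²(nu)/2) <sin²theta>

    with the moments averaged over each sector mask.  Solving the measured
    ratio for cos²(nu) removes the small-cone bias of the reduced formula
    (to which this reduces as the cone width goes to zero).
    """
    if sectors.moments is None:
        return orientation_angle(sectors)
    if sectors.f_left_right <= 0:
        return 90.0
    c_ud, s_ud, c_lr, s_lr = sectors.moments
    ratio = max(sectors.f_up_down, 0.0) / sectors.f_left_right
    num = s_ud - ratio * s_lr
    den = 2.0 * (ratio * (c_lr - 0.5 * s_lr) - (c_ud - 0.5 * s_ud))
    if den == 0:
        return orientation_angle(sectors)
    u = np.clip(num / den, 0.0, 1.0)  # cos²(nu)
    return float(np.degrees(np.arccos(np.sqrt(u))))


class RingOrientationEstimator(BaseEstimator):
    """Estimate the transition-dipole tilt from a polarized GUV image pair.

    Parameters
    ----------
    cone_half_angle : float, default 10.0
        Angular half-width (deg) of the integration sectors.
    g_factor : float, default 0.99
        Instrumental polarization correction used in the total-intensity
        reconstruction ``I_VV + 2 G I_VH``.
    fit_geometry : bool, default False
        Re-localize the ring from the image instead of trusting the
        geometry metadata (center and radius only; the polarization angle
        and ring width always come from the metadata).

    Attributes
    ----------
    nu_ : estimated tilt angle, deg
    ratio_ : sector ratio F_ud / F_lr
    sectors_ : the :class:`SectorIntensities` used
    geometry_ : the geometry actually used
    """

    def __init__(
        self,
        cone_half_angle: float = 10.0,
        g_factor: float = DEFAULT_G_FACTOR,
        fit_geometry: bool = False,
        annulus_sigmas: float = 2.0,
        cone_correction: bool = True,
    ):
        self.cone_half_angle = cone_half_angle
        self.g_factor = g_factor
        self.fit_geometry = fit_geometry
        self.annulus_sigmas = annulus_sigmas
        self.cone_correction = cone_correction

    def fit(self, pair: GuvImagePair, y=None):
        image = pair.total_intensity(self.g_factor)
        geom = pair.geometry
        if self.fit_geometry:
            center, radius = fit_ring(image)
            geom = GuvGeometry(
                center=center,
                radius_px=radius,
                polarization_angle_deg=geom.polarization_angle_deg,
                ring_sigma_px=geom.ring_sigma_px,
                pixel_size_nm=geom.pixel_size_nm,
            )
        sectors = sector_integrate(
            image, geom, self.cone_half_angle, self.annulus_sigmas
        )
        self.sectors_ = sectors
        self.geometry_ = geom
        self.ratio_ = sectors.ratio
        self.nu_ = (
            orientation_angle_finite_cone(sectors)
            if self.cone_correction
            else orientation_angle(sectors)
        )
        return self

    def report(self) -> dict:
        """Machine-readable orientation report."""
        s = self.sectors_
        return {
            "nu_deg": self.nu_,
            "ratio": self.ratio_,
            "F_ud": s.f_up_down,
            "F_lr": s.f_left_right,
            "background": s.background,
            "n_pixels": s.n_pixels_up_down + s.n_pixels_left_right,
        }


# ---------------------------------------------------------------------------
# Fluorescence decay fitting
# ---------------------------------------------------------------------------


class LifetimeModel(BaseEstimator):
    """Multi-exponential fluorescence-decay model fitted to a TCSPC histogram.

    ``I(t) = sum_i A_i exp(-t / tau_i)``, fitted by Poisson-weighted least
    squares (sigma = sqrt(max(counts, 1))); the reported amplitudes are
    normalized fractions ``alpha_i = A_i / sum A`` and the mean lifetime is
    the amplitude-weighted average ``<tau> = sum alpha_i tau_i``.

    Attributes
    ----------
    amplitudes_ : normalized alpha_i (sum to 1), sorted by lifetime
    lifetimes_ : tau_i in the input time units, ascending
    mean_lifetime_ : amplitude-weighted mean lifetime
    """

    def __init__(self, n_components: int = 1, tau_init=None, max_nfev: int = 5000):
        self.n_components = n_components
        self.tau_init = tau_init
        self.max_nfev = max_nfev

    @staticmethod
    def _model(t, amps, taus):
        return np.sum(amps[:, None] * np.exp(-t[None, :] / taus[:, None]), axis=0)

    def fit(self, t, counts):
        t = np.asarray(t, dtype=float)
        counts = np.asarray(counts, dtype=float)
        if self.n_components not in (1, 2, 3):
            raise ValueError("n_components must be 1, 2 or 3")
        if np.any(counts < 0):
            raise ValueError("histogram counts must be nonnegative")
        n = self.n_components
        if self.tau_init is not None:
            tau0 = np.asarray(self.tau_init, dtype=float)
        else:
            # log-spaced over the sampled decay span
            span = t[-1] - t[0] if t[-1] > t[0] else 1.0
            tau0 = np.geomspace(span / 20.0, span / 2.0, n)
        a0 = np.full(n, counts.max() / n if counts.max() > 0 else 1.0)
        sigma = np.sqrt(np.maximum(counts, 1.0))

        def residuals(p):
            amps, ltaus = p[:n], p[n:]
            return (self._model(t, amps, np.exp(ltaus)) - counts) / sigma

        p0 = np.concatenate([a0, np.log(tau0)])
        res = least_squares(residuals, p0, max_nfev=self.max_nfev,
                            bounds=(np.concatenate([np.zeros(n), np.full(n, -20.0)]),
                                    np.full(2 * n, np.inf)))
        if not res.success:
            raise RuntimeError(
                f"lifetime fit did not converge: {res.message}; "
                f"final cost {res.cost:.3g}"
            )
        amps, taus = res.x[:n], np.exp(res.x[n:])
        order = np.argsort(taus)
        amps, taus = amps[order], taus[order]
        total = amps.sum()
        if total <= 0:
            raise RuntimeError("lifetime fit degenerate: zero total amplitude")
        self.amplitudes_ = amps / total
        self.lifetimes_ = taus
        self.mean_lifetime_ = float(np.dot(self.amplitudes_, taus))
        self.cost_ = float(res.cost)
        return self

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        scale = self.amplitudes_  # unit total amplitude
        return self._model(t, scale, self.lifetimes_)


def fit_lifetimes(t, counts, n_components: int = 1, tau_init=None) -> LifetimeModel:
    """Fit a multi-exponential decay; functional wrapper of :class:`LifetimeModel`."""
    return LifetimeModel(n_components=n_components, tau_init=tau_init).fit(t, counts)


# ---------------------------------------------------------------------------
# Confocal volume and concentration bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfocalGeometry:
    """Ellipsoidal confocal observation volume: lateral and axial radii (nm)."""

    x0_nm: float
    z0_nm: float

    def __post_init__(self) -> None:
        if self.x0_nm <= 0 or self.z0_nm <= 0:
            raise ValueError("confocal radii must be positive")


def confocal_volume(geometry: ConfocalGeometry) -> float:
    """Effective confocal volume ``V = pi^(3/2) x0^2 z0`` in femtoliters.

    The observation spot is approximated as a 3-D Gaussian ellipsoid with
    lateral 1/e² radius ``x0`` and axial radius ``z0`` (1 fl = 10^9 nm³).
    """
    v_nm3 = np.pi**1.5 * geometry.x0_nm**2 * geometry.z0_nm
    return float(v_nm3 / 1e9)


def mol_percent_from_surface_density(
    area_per_pigment_nm2: float = 62.0,
    area_per_lipid_nm2: float = 0.6,
    leaflets: int = 2,
) -> float:
    """Pigment concentration (mol% vs. lipid) from a membrane surface density.

    One membrane-spanning pigment per ``area_per_pigment_nm2`` of membrane
    surface shares that patch with ``leaflets * area / area_per_lipid``
    lipids (the pigment spans both monolayers, the lipids only one).  The
    literature macular density of 1 per 62 nm² with a 0.6 nm² lipid area
    gives ~0.48 mol%.
    """
    if min(area_per_pigment_nm2, area_per_lipid_nm2) <= 0 or leaflets < 1:
        raise ValueError("areas must be positive and leaflets >= 1")
    lipids = leaflets * area_per_pigment_nm2 / area_per_lipid_nm2
    return 100.0 / lipids


# ---------------------------------------------------------------------------
# Raman band integration
# ---------------------------------------------------------------------------


def integrate_band(
    cube: RamanCube,
    lo: float = 1500.0,
    hi: float = 1550.0,
    subtract_baseline: bool = True,
) -> np.ndarray:
    """Per-pixel band integral with a linear baseline anchored at the edges.

    For each pixel spectrum, a straight baseline through the values at
    ``lo`` and ``hi`` (cm^-1) is subtracted and the remainder integrated
    over [lo, hi] by the trapezoidal rule; a flat spectrum therefore
    integrates to zero and an isolated band to (approximately) its area.
    With ``subtract_baseline=False`` the raw trapezoidal integral is
    returned.
    """
    wn = cube.wavenumbers
    if not (wn[0] <= lo < hi <= wn[-1]):
        raise ValueError(f"band [{lo}, {hi}] cm^-1 falls outside the axis")
    sel = (wn >= lo) & (wn <= hi)
    x = wn[sel]
    spectra = cube.data[..., sel]
    if not subtract_baseline:
        return np.trapezoid(spectra, x, axis=-1)
    flat = cube.data.reshape(-1, wn.size)
    y_lo = np.array([np.interp(lo, wn, s) for s in flat]).reshape(cube.data.shape[:-1])
    y_hi = np.array([np.interp(hi, wn, s) for s in flat]).reshape(cube.data.shape[:-1])
    t = (x - lo) / (hi - lo)
    baseline = y_lo[..., None] * (1 - t) + y_hi[..., None] * t
    return np.trapezoid(spectra - baseline, x, axis=-1)
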