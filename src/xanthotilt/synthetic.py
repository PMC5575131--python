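"""Synthetic inputs for both analysis routes.

The generators stand in for the instruments the real study used: a polarized
confocal microscope imaging GUV equatorial cross-sections, a resonance-Raman
mapper, and a molecular-dynamics engine producing umbrella-sampling windows
and membrane trajectory frames.  Each generator produces data with exactly the
statistical structure the downstream analysis assumes (cos^2 photoselection,
Boltzmann-distributed biased sampling, binomially occupied hydrogen bonds), so
analysis code can be validated against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .constants import DEFAULT_TEMPERATURE_K, rt_kcal_per_mol
from .membrane import MembraneFrame
from .umbrella import UmbrellaWindow

# ---------------------------------------------------------------------------
# GUV image synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuvGeometry:
    """Geometry of an equatorial GUV ring in an image.

    ``polarization_angle_deg`` is the in-plane angle of the excitation
    electric vector measured from the image x-axis; ``ring_sigma_px`` is the
    effective Gaussian radial half-width of the ring (membrane cross-section
    convolved with the PSF).
    """

    center: tuple[float, float]  # (row, col)
    radius_px: float
    polarization_angle_deg: float = 90.0
    ring_sigma_px: float = 2.0
    pixel_size_nm: float | None = None

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "radius_px": self.radius_px,
            "polarization_angle_deg": self.polarization_angle_deg,
            "ring_sigma_px": self.ring_sigma_px,
            "pixel_size_nm": self.pixel_size_nm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GuvGeometry":
        return cls(
            center=tuple(d["center"]),
            radius_px=float(d["radius_px"]),
            polarization_angle_deg=float(d.get("polarization_angle_deg", 90.0)),
            ring_sigma_px=float(d.get("ring_sigma_px", 2.0)),
            pixel_size_nm=d.get("pixel_size_nm"),
        )


@dataclass
class GuvImagePair:
    """Two co-registered polarized detection channels of a GUV ring.

    ``i_vv`` is the channel analyzing emission parallel to the (vertical)
    excitation polarization, ``i_vh`` the perpendicular channel.
    """

    i_vv: np.ndarray
    i_vh: np.ndarray
    geometry: GuvGeometry
    detection_mode: str = "sum_channels"

    def total_intensity(self, g_factor: float = 1.0) -> np.ndarray:
        """Total-intensity reconstruction ``I_VV + 2 G I_VH``."""
        return self.i_vv + 2.0 * g_factor * self.i_vh


@dataclass(frozen=True)
class GuvRenderSpec:
    """Parameters for rendering a synthetic GUV equatorial image.

    ``tilt_nu`` is the angle (deg) between the transition dipole and the
    local membrane normal; the dipole azimuth about the normal is assumed
    uniform (free rotation of the chromophore about the bilayer normal).
    """

    tilt_nu: float
    ring_radius_px: float = 60.0
    ring_width_px: float = 1.5
    psf_sigma_px: float = 1.5
    photons_per_px: float = 8.0
    polarization_angle_deg: float = 90.0
    image_shape: tuple[int, int] = (160, 160)
    detection_mode: str = "sum_channels"
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt_nu <= 90.0:
            raise ValueError("tilt_nu must lie in [0, 90] degrees")
        if self.ring_radius_px <= 0 or self.ring_width_px <= 0:
            raise ValueError("ring radius and width must be positive")
        if self.psf_sigma_px < 0:
            raise ValueError("psf_sigma_px must be nonnegative")
        if self.photons_per_px < 0:
            raise ValueError("photon budget must be nonnegative")
        if self.detection_mode not in ("sum_channels", "vv_vh_split"):
            raise ValueError(f"unknown detection_mode {self.detection_mode!r}")
        margin = self.ring_radius_px + 4 * (self.ring_width_px + self.psf_sigma_px)
        if margin > min(self.image_shape) / 2.0:
            raise ValueError("ring (plus PSF margin) does not fit inside the frame")


def photoselection_intensity(theta_deg, nu_deg: float):
    """Expected ring intensity vs. in-plane angle from the polarization axis.

    For an absorption dipole tilted by ``nu`` from the local membrane normal
    and uniformly distributed in azimuth, the azimuth-averaged absorption
    probability at ring position ``theta`` (measured from the excitation
    polarization axis) is::

        I(theta) ∝ cos²nu · cos²theta + (sin²nu / 2) · sin²theta

    At the magic angle (cos²nu = 1/3) the two coefficients coincide and the
    ring is uniform.
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    nu = np.deg2rad(nu_deg)
    return np.cos(nu) ** 2 * np.cos(theta) ** 2 + 0.5 * np.sin(nu) ** 2 * np.sin(theta) ** 2


def _ring_fields(shape: tuple[int, int], center: tuple[float, float], pol_deg: float):
    """Per-pixel radius and in-plane angle relative to the polarization axis."""
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    r = np.hypot(rows, cols)
    # Image angle from +x (col) axis; rows increase downward but the sign of
    # the angle is irrelevant to the even (cos²/sin²) photoselection law.
    ang = np.arctan2(rows, cols) - np.deg2rad(pol_deg)
    return r, ang


def _split_channel_laws(theta: np.ndarray, nu_deg: float, n_psi: int = 64):
    """Azimuth-averaged VV and VH channel intensities at ring angle theta.

    The emission dipole is taken collinear with the absorption dipole (polyene
    assumption).  Averages over the dipole azimuth ``psi`` about the local
    normal are computed on an equispaced grid, which integrates the low-order
    trigonometric polynomial exactly.
    """
    nu = np.deg2rad(nu_deg)
    psi = (np.arange(n_psi) + 0.5) * (2 * np.pi / n_psi)
    cos_t, sin_t = np.cos(theta)[..., None], np.sin(theta)[..., None]
    # Frame: x along excitation polarization, y in-plane perpendicular, z optical axis.
    mu_x = np.cos(nu) * cos_t - np.sin(nu) * np.cos(psi) * sin_t
    mu_y = np.cos(nu) * sin_t + np.sin(nu) * np.cos(psi) * cos_t
    i_vv = np.mean(mu_x**4, axis=-1)
    i_vh = np.mean(mu_x**2 * mu_y**2, axis=-1)
    return i_vv, i_vh


def render_guv_image(spec: GuvRenderSpec) -> GuvImagePair:
    """Render a two-channel polarized image of a GUV equatorial ring.

    The noise-free expected total intensity follows the azimuth-averaged
    photoselection law of :func:`photoselection_intensity`; the radial
    cross-section of the (sub-resolution) membrane is Gaussian of width
    ``ring_width_px``; the image is then blurred with a Gaussian PSF and,
    if ``shot_noise``, Poisson noise is applied per pixel and channel.
    """
    center = ((spec.image_shape[0] - 1) / 2.0, (spec.image_shape[1] - 1) / 2.0)
    r, ang = _ring_fields(spec.image_shape, center, spec.polarization_angle_deg)
    radial = np.exp(-0.5 * ((r - spec.ring_radius_px) / spec.ring_width_px) ** 2)

    if spec.detection_mode == "sum_channels":
        law = photoselection_intensity(np.rad2deg(ang), spec.tilt_nu)
        total = spec.photons_per_px * law * radial
        # Even split consistent with the I_VV + 2 I_VH total reconstruction.
        ch_vv, ch_vh = total / 3.0, total / 3.0
    else:
        law_vv, law_vh = _split_channel_laws(ang, spec.tilt_nu)
        ch_vv = spec.photons_per_px * law_vv * radial
        ch_vh = spec.photons_per_px * law_vh * radial

    if spec.psf_sigma_px > 0:
        ch_vv = ndimage.gaussian_filter(ch_vv, spec.psf_sigma_px)
        ch_vh = ndimage.gaussian_filter(ch_vh, spec.psf_sigma_px)

    if spec.shot_noise:
        rng = np.random.default_rng(spec.seed)
        ch_vv = rng.poisson(ch_vv).astype(float)
        ch_vh = rng.poisson(ch_vh).astype(float)

    sigma_eff = float(np.hypot(spec.ring_width_px, spec.psf_sigma_px))
    geom = GuvGeometry(
        center=center,
        radius_px=spec.ring_radius_px,
        polarization_angle_deg=spec.polarization_angle_deg,
        ring_sigma_px=sigma_eff,
    )
    return GuvImagePair(ch_vv, ch_vh, geom, spec.detection_mode)


def dipole_mc_intensity(
    theta_deg: float, nu_deg: float, n_samples: int = 1_000_000, seed: int = 0
) -> float:
    """Brute-force Monte-Carlo oracle for the photoselection law.

    Draws ``n_samples`` dipole azimuths ``psi`` uniformly, builds
    ``mu = cos(nu) n + sin(nu)(cos(psi) t1 + sin(psi) t2)`` and averages the
    absorption probability ``(mu . E)^2``.  Used only as an independent
    cross-check of :func:`photoselection_intensity`.
    """
    rng = np.random.default_rng(seed)
    psi = rng.uniform(0.0, 2 * np.pi, n_samples)
    theta, nu = np.deg2rad(theta_deg), np.deg2rad(nu_deg)
    # E along x; n = (cos t, sin t, 0), t1 = (-sin t, cos t, 0), t2 = z.
    mu_dot_e = np.cos(nu) * np.cos(theta) - np.sin(nu) * np.cos(psi) * np.sin(theta)
    return float(np.mean(mu_dot_e**2))


# ---------------------------------------------------------------------------
# Overdamped Langevin sampling of a 1-D PMF under harmonic bias
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PmfSpec:
    """A prescribed 1-D potential of mean force used as simulation ground truth.

    ``grid`` (Å, strictly ascending) and ``values`` (kcal/mol) tabulate the
    free energy over the bilayer-normal distance coordinate; ``friction``
    (inverse-time units, with kT/friction the diffusion coefficient) and
    ``dt`` control the overdamped dynamics.
    """

    grid: np.ndarray
    values: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K
    friction: float = 1.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be 1-D and strictly ascending")
        if values.shape != grid.shape or not np.all(np.isfinite(values)):
            raise ValueError("values must be finite and match the grid")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.friction <= 0 or self.dt <= 0:
            raise ValueError("friction and dt must be positive")

    def energy(self, z):
        return CubicSpline(self.grid, self.values)(z)


class LangevinDivergenceError(RuntimeError):
    """Raised when the Euler–Maruyama trajectory escapes the PMF grid span."""


@njit(cache=True)
def _em_trajectory(z0, n_steps, stride, dt, gamma, rt, grid, force_grid,
                   bias_center, spring_k, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    lo, hi = grid[0], grid[-1]
    span = hi - lo
    amp = np.sqrt(2.0 * rt * dt / gamma)
    n_rec = n_steps // stride
    out = np.empty(n_rec)
    z = z0
    j = 0
    for i in range(n_steps):
        f = np.interp(z, grid, force_grid) - spring_k * (z - bias_center)
        z = z + f * dt / gamma + amp * np.random.normal()
        if z < lo - 0.2 * span or z > hi + 0.2 * span:
            return out[:j], 1
        # reflecting walls at the grid edges
        if z < lo:
            z = 2.0 * lo - z
        elif z > hi:
            z = 2.0 * hi - z
        if (i + 1) % stride == 0:
            out[j] = z
            j += 1
    return out, 0


def simulate_window(
    pmf: PmfSpec,
    bias_center: float,
    spring_k: float,
    n_steps: int,
    seed: int,
    stride: int = 10,
    burn_in_frac: float = 0.1,
    z_init: float | None = None,
) -> UmbrellaWindow:
    """Sample one umbrella window by overdamped Langevin dynamics.

    The walker moves on ``U(z) = PMF(z) + k/2 (z - z0)^2`` with the
    Euler–Maruyama update and reflecting walls at the grid edges; its
    stationary distribution converges to ``exp(-U/RT)`` for small ``dt``.
    Every ``stride``-th position is recorded and the first ``burn_in_frac``
    of the record is discarded.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    if spring_k < 0:
        raise ValueError("spring_k must be nonnegative")
    grid = pmf.grid
    if z_init is None:
        z_init = float(np.clip(bias_center, grid[0], grid[-1]))
    rt = rt_kcal_per_mol(pmf.temperature)
    # Force from the PMF spline, tabulated on a fine grid for the kernel.
    fine = np.linspace(grid[0], grid[-1], max(4 * grid.size, 1000))
    force = -CubicSpline(grid, pmf.values)(fine, 1)
    samples, flag = _em_trajectory(
        z_init, int(n_steps), int(stride), pmf.dt, pmf.friction, rt,
        fine, force, float(bias_center), float(spring_k), int(seed) & 0x7FFFFFFF,
    )
    if flag:
        raise LangevinDivergenceError(
            "trajectory left the PMF grid span by >20%; decrease dt"
        )
    n_burn = int(burn_in_frac * samples.size)
    return UmbrellaWindow(
        center=float(bias_center),
        spring_k=float(spring_k),
        samples=samples[n_burn:].copy(),
        temperature=pmf.temperature,
    )


def simulate_umbrella_run(
    pmf: PmfSpec,
    centers: Sequence[float],
    spring_k: float = 3.0,
    n_steps: int = 200_000,
    seed: int = 0,
    stride: int = 10,
) -> list[UmbrellaWindow]:
    """Simulate a full set of umbrella windows with per-window derived seeds."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(len(centers))]
    return [
        simulate_window(pmf, c, spring_k, n_steps, s, stride=stride)
        for c, s in zip(centers, seeds)
    ]


def paper_window_centers() -> np.ndarray:
    """The 11 bias centers of the study layout: 0..10.8 Å step 1.2, plus 11.8 Å."""
    return np.append(np.arange(0.0, 10.81, 1.2), 11.8)


# ---------------------------------------------------------------------------
# Toy membrane frames
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyMembraneSpec:
    """Parameters for generating toy membrane trajectory frames.

    Each frame carries a rigid xanthophyll axis tilted ``tilt_phi`` degrees
    from the bilayer normal with terminal rings ``ring_separation`` Å apart,
    ``n_hbond_sites`` hydroxyl donor sites each hydrogen-bonded with
    probability ``hbond_fraction_target``, and lipid chain atoms filling the
    hydrophobic slab ``|z| < half_thickness``.
    """

    n_frames: int = 500
    hbond_fraction_target: float = 0.5
    half_thickness: float = 12.4
    ring_separation: float = 32.6
    tilt_phi: float = 40.0
    n_hbond_sites: int = 2
    n_chain_atoms: int = 60
    box_size: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if not 0.0 <= self.hbond_fraction_target <= 1.0:
            raise ValueError("hbond_fraction_target must lie in [0, 1]")
        if self.half_thickness <= 0 or self.ring_separation <= 0:
            raise ValueError("lengths must be positive")
        if not 0.0 <= self.tilt_phi <= 90.0:
            raise ValueError("tilt_phi must lie in [0, 90] degrees")
        if self.ring_separation > 2.0 * self.box_size:
            raise ValueError("ring_separation exceeds twice the frame box")


def generate_membrane_frames(spec: ToyMembraneSpec) -> list[MembraneFrame]:
    """Generate membrane frames with prescribed tilt, ring span and H-bond rate.

    Hydrogen-bond sites are drawn independently per frame: a bonded site is
    built at donor–acceptor distance 2.9 Å and donor–H–acceptor angle 180°
    (satisfying any conventional geometric criterion), an unbonded one at
    5.0 Å, so the empirical bonded fraction is binomial around the target.
    """
    rng = np.random.default_rng(spec.seed)
    phi = np.deg2rad(spec.tilt_phi)
    orientation = "horizontal" if spec.tilt_phi > 70.0 else "vertical"
    frames: list[MembraneFrame] = []
    for _ in range(spec.n_frames):
        azim = rng.uniform(0.0, 2 * np.pi)
        axis = np.array(
            [np.sin(phi) * np.cos(azim), np.sin(phi) * np.sin(azim), np.cos(phi)]
        )
        half = 0.5 * spec.ring_separation * axis
        ring1, ring2 = half, -half
        chain_z = rng.uniform(-spec.half_thickness, spec.half_thickness,
                              spec.n_chain_atoms)
        donors = np.empty((spec.n_hbond_sites, 3))
        hydrogens = np.empty_like(donors)
        acceptors = np.empty_like(donors)
        for s in range(spec.n_hbond_sites):
            base = ring1 if s % 2 == 0 else ring2
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            d_da = 2.9 if rng.uniform() < spec.hbond_fraction_target else 5.0
            donors[s] = base
            hydrogens[s] = base + 1.0 * u
            acceptors[s] = base + d_da * u
        frames.append(
            MembraneFrame(
                ring1=ring1,
                ring2=ring2,
                chain_z=chain_z,
                donors=donors,
                hydrogens=hydrogens,
                acceptors=acceptors,
                orientation=orientation,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Hyperspectral Raman map synthesis
# ---------------------------------------------------------------------------


@dataclass
class RamanCube:
    """A hyperspectral map: ``data[row, col, k]`` vs. ``wavenumbers[k]`` (cm^-1)."""

    data: np.ndarray
    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != self.wavenumbers.size:
            raise ValueError("data must be (ny, nx, n_wavenumbers)")


def render_raman_map(
    geometry: GuvGeometry,
    tilt_nu: float,
    image_shape: tuple[int, int] = (48, 48),
    wavenumber_range: tuple[float, float] = (350.0, 1900.0),
    wavenumber_step: float = 2.0,
    band_center: float = 1520.0,
    band_width: float = 8.0,
    band_amplitude: float = 30.0,
    baseline: float = 2.0,
    ring_width_px: float = 1.5,
    shot_noise: bool = True,
    seed: int = 0,
) -> RamanCube:
    """Render a resonance-Raman hyperspectral map of a GUV ring.

    Each pixel spectrum is ``baseline`` plus a Gaussian C=C stretch band at
    ``band_center`` whose amplitude carries the same cos² photoselection
    modulation as the fluorescence renderer — the resonance condition couples
    the scattering to the electronic transition dipole, so pigment appears in
    the sectors where that dipole aligns with the laser polarization.
    """
    wn = np.arange(wavenumber_range[0], wavenumber_range[1] + 0.5 * wavenumber_step,
                   wavenumber_step)
    if not (wn[0] <= band_center - 2 * band_width
            and band_center + 2 * band_width <= wn[-1]):
        raise ValueError("Raman band falls outside the wavenumber axis")
    r, ang = _ring_fields(image_shape, geometry.center, geometry.polarization_angle_deg)
    law = photoselection_intensity(np.rad2deg(ang), tilt_nu)
    radial = np.exp(-0.5 * ((r - geometry.radius_px) / ring_width_px) ** 2)
    amp = band_amplitude * law * radial
    band = np.exp(-0.5 * ((wn - band_center) / band_width) ** 2)
    cube = baseline + amp[..., None] * band[None, None, :]
    if shot_noise:
        rng = np.random.default_rng(seed)
        cube = rng.poisson(cube).astype(float)
    return RamanCube(cube, wn)
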