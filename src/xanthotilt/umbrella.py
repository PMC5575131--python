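"""Free-energy reconstruction from umbrella-sampling windows.

Implements the weighted histogram analysis method (WHAM) for harmonically
biased windows over the bilayer-normal distance coordinate, an
autocorrelation-aware moving-block bootstrap for per-bin uncertainties, the
one-to-one mapping of the distance profile onto the chromophore tilt angle
phi, and the derived observables: Boltzmann angle distribution, mean tilt,
well depth of the horizontal arrangement, and equilibrium population ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .constants import DEFAULT_ELL_ANGSTROM, DEFAULT_TEMPERATURE_K, rt_kcal_per_mol

# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class UmbrellaWindow:
    """One biased time series: samples of the reaction coordinate under a
    harmonic restraint ``k/2 (z - center)^2``.

    Units: Å for ``center`` and ``samples``, kcal mol^-1 Å^-2 for
    ``spring_k``, K for ``temperature``.  ``spring_k = 0`` denotes an
    unbiased window.
    """

    center: float
    spring_k: float
    samples: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.spring_k < 0:
            raise ValueError("spring_k must be nonnegative")
        if self.samples.size == 0 or not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be nonempty and finite")

    def bias_energy(self, z) -> np.ndarray:
        return 0.5 * self.spring_k * (np.asarray(z, dtype=float) - self.center) ** 2


@dataclass
class FreeEnergyProfile:
    """Tabulated free energy over a scalar coordinate, min-shifted to zero.

    ``coordinate_kind`` is ``"z_distance"`` (Å) or ``"phi_angle"`` (deg);
    ``values`` and ``stderr`` are in kcal/mol; unsampled bins carry NaN.
    """

    grid: np.ndarray
    values: np.ndarray
    stderr: np.ndarray | None = None
    coordinate_kind: str = "z_distance"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be matching 1-D arrays")
        diffs = np.diff(self.grid)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("grid must be strictly monotone")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if self.stderr.shape != self.grid.shape:
                raise ValueError("stderr must match the grid")
            if np.any(self.stderr[np.isfinite(self.stderr)] < 0):
                raise ValueError("stderr must be nonnegative")
        finite = np.isfinite(self.values)
        if finite.any():
            self.values = self.values - np.nanmin(self.values[finite])

    @property
    def argmin(self) -> float:
        """Coordinate of the free-energy minimum."""
        return float(self.grid[np.nanargmin(self.values)])


@dataclass
class AngleDistribution:
    """Normalized probability density of the tilt angle phi on [0°, 90°]."""

    grid: np.ndarray
    density: np.ndarray
    mean_angle: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")


class WhamConnectivityError(RuntimeError):
    """Adjacent windows share no populated histogram bins."""


class WhamConvergenceError(RuntimeError):
    """Self-consistent iteration failed to reach tolerance."""


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------


class WhamEstimator(BaseEstimator):
    """Weighted histogram analysis method for harmonically biased windows.

    Solves the standard self-consistent WHAM equations

        p(b) = sum_i n_i(b) / sum_i N_i exp(f_i - w_i(b)/RT)
        exp(-f_i) = sum_b p(b) exp(-w_i(b)/RT)

    iterating the dimensionless window free energies ``f_i`` until the
    largest change of ``RT f_i`` falls below ``tol`` (kcal/mol).  The
    unbiased profile is ``G(b) = -RT ln p(b)``, shifted so its minimum is 0.

    Parameters
    ----------
    bin_width : float, default 0.1
        Histogram bin width in Å.
    z_range : tuple or None
        Coordinate range; by default spans the pooled samples.
    tol : float, default 1e-7
        Convergence tolerance on the window offsets, kcal/mol.
    max_iter : int, default 100_000
    temperature : float or None
        Overrides the windows' temperature if given.

    Attributes
    ----------
    grid_ : bin centers (Å)
    free_energy_ : G(z) in kcal/mol, min-shifted; NaN on empty bins
    window_offsets_ : converged per-window free energies, kcal/mol
    stderr_ : per-bin bootstrap standard error (after ``bootstrap``)
    n_iter_ : iterations used
    """

    def __init__(
        self,
        bin_width: float = 0.1,
        z_range: tuple[float, float] | None = None,
        tol: float = 1e-7,
        max_iter: int = 100_000,
        temperature: float | None = None,
    ):
        self.bin_width = bin_width
        self.z_range = z_range
        self.tol = tol
        self.max_iter = max_iter
        self.temperature = temperature

    # -- internal ----------------------------------------------------------

    def _setup(self, windows: Sequence[UmbrellaWindow]):
        if len(windows) == 0:
            raise ValueError("need at least one umbrella window")
        temp = self.temperature or windows[0].temperature
        rt = rt_kcal_per_mol(temp)
        if self.z_range is not None:
            lo, hi = self.z_range
        else:
            lo = min(w.samples.min() for w in windows)
            hi = max(w.samples.max() for w in windows)
        n_bins = max(int(np.ceil((hi - lo) / self.bin_width)), 1)
        edges = lo + self.bin_width * np.arange(n_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = np.stack(
            [np.histogram(w.samples, bins=edges)[0] for w in windows]
        ).astype(float)
        log_c = np.stack([-w.bias_energy(centers) / rt for w in windows])
        return rt, edges, centers, counts, log_c

    @staticmethod
    def _check_connectivity(
        windows: Sequence[UmbrellaWindow], counts: np.ndarray
    ) -> None:
        if len(windows) < 2:
            return
        order = np.argsort([w.center for w in windows])
        report = []
        for a, b in zip(order[:-1], order[1:]):
            overlap = int(np.sum((counts[a] > 0) & (counts[b] > 0)))
            report.append((windows[a].center, windows[b].center, overlap))
        bad = [r for r in report if r[2] == 0]
        if bad:
            lines = ", ".join(f"{a:g}–{b:g} Å: {n} bins" for a, b, n in bad)
            raise WhamConnectivityError(
                f"umbrella histograms are disconnected (no overlap between "
                f"adjacent windows: {lines})"
            )

    def _solve(self, counts, log_c, rt, init_offsets=None):
        n_win = counts.shape[0]
        log_ni = np.where(counts > 0, np.log(np.maximum(counts, 1e-300)), -np.inf)
        log_num = logsumexp(log_ni, axis=0)  # log sum_i n_i(b)
        log_n_tot = np.log(counts.sum(axis=1))  # log N_i
        f = np.zeros(n_win) if init_offsets is None else np.asarray(
            init_offsets, float
        ) / rt
        sampled = np.isfinite(log_num)
        for it in range(1, self.max_iter + 1):
            # log p(b) up to a constant
            log_den = logsumexp(log_n_tot[:, None] + f[:, None] + log_c, axis=0)
            log_p = np.where(sampled, log_num - log_den, -np.inf)
            f_new = -logsumexp(log_p[None, :] + log_c, axis=1)
            f_new = f_new - f_new[0]
            delta = np.max(np.abs(f_new - f)) * rt
            f = f_new
            if delta < self.tol:
                return log_p, f, it
        raise WhamConvergenceError(
            f"WHAM did not converge in {self.max_iter} iterations "
            f"(last offset change {delta:.3g} kcal/mol)"
        )

    # -- public API --------------------------------------------------------

    def fit(self, windows: Sequence[UmbrellaWindow], init_offsets=None):
        """Estimate the unbiased free-energy profile from biased windows."""
        windows = list(windows)
        rt, edges, centers, counts, log_c = self._setup(windows)
        self._check_connectivity(windows, counts)
        log_p, f, n_iter = self._solve(counts, log_c, rt, init_offsets)
        g = np.where(np.isfinite(log_p), -rt * log_p, np.nan)
        self.rt_ = rt
        self.bin_edges_ = edges
        self.grid_ = centers
        self.counts_ = counts
        self.free_energy_ = g - np.nanmin(g)
        self.window_offsets_ = f * rt
        self.n_iter_ = n_iter
        self.stderr_ = None
        self._windows = windows
        return self

    @property
    def profile_(self) -> FreeEnergyProfile:
        return FreeEnergyProfile(
            self.grid_, self.free_energy_, self.stderr_, "z_distance"
        )

    def bootstrap(self, n_boot: int = 100, seed: int = 0) -> np.ndarray:
        """Moving-block bootstrap standard error of the profile, per bin.

        Each window is resampled in contiguous blocks of length
        ``ceil(2 tau_int)`` (tau_int from the initial-positive-sequence
        autocorrelation estimator), WHAM is re-solved per replicate, and the
        per-bin standard deviation across replicates (after re-applying the
        min-shift) is stored in ``stderr_``.
        """
        if n_boot < 2:
            raise ValueError("n_boot must be at least 2")
        if not hasattr(self, "grid_"):
            raise RuntimeError("call fit() before bootstrap()")
        rng = np.random.default_rng(seed)
        blocks = [
            int(np.ceil(2.0 * integrated_autocorrelation_time(w.samples)))
            for w in self._windows
        ]
        for w, b in zip(self._windows, blocks):
            if w.samples.size < 2 * b:
                raise ValueError(
                    f"window at {w.center:g} Å is too short for block "
                    f"resampling ({w.samples.size} samples, block {b})"
                )
        rt = self.rt_
        log_c = np.stack(
            [-w.bias_energy(self.grid_) / rt for w in self._windows]
        )
        reps = np.empty((n_boot, self.grid_.size))
        for r in range(n_boot):
            counts = np.stack(
                [
                    np.histogram(
                        _moving_block_resample(w.samples, b, rng),
                        bins=self.bin_edges_,
                    )[0]
                    for w, b in zip(self._windows, blocks)
                ]
            ).astype(float)
            log_p, _, _ = self._solve(counts, log_c, rt)
            g = np.where(np.isfinite(log_p), -rt * log_p, np.nan)
            reps[r] = g - np.nanmin(g)
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            self.stderr_ = np.nanstd(reps, axis=0, ddof=1)
        self.bootstrap_profiles_ = reps
        return self.stderr_


def _moving_block_resample(x: np.ndarray, block: int, rng) -> np.ndarray:
    n = x.size
    if block >= n:
        return x.copy()
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n - block + 1, n_blocks)
    idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n]
    return x[idx]


def wham(
    windows: Sequence[UmbrellaWindow],
    bin_width: float = 0.1,
    z_range: tuple[float, float] | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    temperature: float | None = None,
) -> FreeEnergyProfile:
    """Functional wrapper around :class:`WhamEstimator`."""
    est = WhamEstimator(bin_width, z_range, tol, max_iter, temperature)
    return est.fit(windows).profile_


def bootstrap_uncertainty(
    windows: Sequence[UmbrellaWindow],
    n_boot: int = 100,
    seed: int = 0,
    **wham_kwargs,
) -> np.ndarray:
    """Per-bin bootstrap standard error of the WHAM profile (kcal/mol)."""
    est = WhamEstimator(**wham_kwargs)
    est.fit(windows)
    return est.bootstrap(n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Autocorrelation
# ---------------------------------------------------------------------------


def integrated_autocorrelation_time(x: np.ndarray) -> float:
    """Integrated autocorrelation time by the initial-positive-sequence rule.

    ``tau_int = 1 + 2 sum_k rho_k``, truncating where the sum of adjacent
    autocorrelation pairs ``rho_{2m} + rho_{2m+1}`` first turns nonpositive;
    equals 1 for white noise.  Autocovariances are computed by FFT.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 1.0
    xc = x - x.mean()
    var = np.dot(xc, xc) / n
    if var == 0:
        return 1.0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n] / n
    rho = acov / acov[0]
    tau = 1.0
    m = 0
    while 2 * m + 2 < n:
        pair = rho[2 * m + 1] + rho[2 * m + 2]
        if pair <= 0:
            break
        tau += 2.0 * pair
        m += 1
    return float(max(tau, 1.0))


# ---------------------------------------------------------------------------
# Distance -> angle mapping and derived observables
# ---------------------------------------------------------------------------


def map_z_to_angle(
    profile: FreeEnergyProfile, ell: float = DEFAULT_ELL_ANGSTROM
) -> FreeEnergyProfile:
    """Map a distance profile onto the tilt angle by plain substitution.

    The reaction coordinate ``z`` is the bilayer-normal projection of a rigid
    lever of length ``ell``, so ``phi = arccos(z / ell)`` in degrees:
    ``z = ell`` is vertical (phi = 0°), ``z = 0`` horizontal (phi = 90°).
    The free-energy values and their standard errors are carried through
    unchanged (one-to-one mapping of the curve, no Jacobian).
    """
    z = profile.grid
    if np.any(z < -1e-9) or np.any(z > ell * (1 + 1e-9)):
        raise ValueError(f"z grid must lie within [0, ell={ell}] Å")
    phi = np.degrees(np.arccos(np.clip(z / ell, 0.0, 1.0)))
    order = np.argsort(phi)
    stderr = None if profile.stderr is None else profile.stderr[order]
    return FreeEnergyProfile(phi[order], profile.values[order], stderr, "phi_angle")


def angle_distribution(
    profile: FreeEnergyProfile,
    temperature: float = DEFAULT_TEMPERATURE_K,
    jacobian: bool = True,
) -> AngleDistribution:
    """Boltzmann probability density of the tilt angle from G(phi).

    ``p(phi) ∝ exp(-G/RT) sin(phi)`` with the geometric (solid-angle)
    Jacobian on — the default, appropriate for an axis free to point
    anywhere on the hemisphere — or ``∝ exp(-G/RT)`` with it off.
    Normalized to unit integral over the grid; unsampled (NaN/inf) bins
    contribute zero probability.
    """
    if profile.coordinate_kind != "phi_angle":
        raise ValueError("angle_distribution expects a phi-angle profile")
    phi = profile.grid
    g = profile.values
    rt = rt_kcal_per_mol(temperature)
    finite = np.isfinite(g)
    if not finite.any():
        raise ValueError("free energy is undefined on the whole grid")
    w = np.zeros_like(phi)
    w[finite] = np.exp(-(g[finite] - np.nanmin(g[finite])) / rt)
    if jacobian:
        w = w * np.sin(np.deg2rad(phi))
    norm = np.trapezoid(w, phi)
    if norm <= 0:
        raise ValueError("degenerate angle distribution")
    p = w / norm
    mean = float(np.trapezoid(phi * p, phi))
    return AngleDistribution(phi, p, mean)


def population_ratio(
    delta_g: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Equilibrium population ratio ``exp(delta_g / RT)``.

    With ``delta_g`` the free-energy penalty difference (kcal/mol) of some
    arrangement between two species, this is how many times more populated
    that arrangement is for the species with the smaller penalty.
    """
    return float(np.exp(delta_g / rt_kcal_per_mol(temperature)))


def classify_orientation(phi: float, threshold: float = 70.0) -> str:
    """Classify a tilt angle: ``"horizontal"`` iff phi > 70°, else vertical."""
    if not 0.0 <= phi <= 90.0:
        raise ValueError(f"phi must lie in [0, 90] degrees, got {phi}")
    return "horizontal" if phi > threshold else "vertical"


def horizontal_penalty(
    profile: FreeEnergyProfile, threshold: float = 70.0
) -> float:
    """Free-energy cost of the horizontal arrangement (phi > threshold):
    minimum of G over the horizontal region, relative to the global minimum."""
    if profile.coordinate_kind != "phi_angle":
        raise ValueError("horizontal_penalty expects a phi-angle profile")
    region = profile.grid > threshold
    if not np.any(region & np.isfinite(profile.values)):
        raise ValueError("no sampled bins in the horizontal region")
    return float(np.nanmin(profile.values[region]))
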