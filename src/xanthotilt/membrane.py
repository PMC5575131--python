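"""Membrane structural analyses: hydrophobic thickness, projected ring–ring
distance, and hydrogen-bond occupancy by orientation class.

These are the quantities that connect the tilt of a transmembrane xanthophyll
to the bilayer it sits in: the hydrophobic core thickness ``D_h`` sets the
span available between the two polar interfaces, the bilayer-normal
projection of the terminal-ring separation measures how the molecule bridges
that span, and hydrogen bonding of the terminal hydroxyls to lipid headgroups
stabilizes the vertical arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass
class MembraneFrame:
    """One trajectory frame: ring centers, chain-atom z, and H-bond triplets.

    ``donors``, ``hydrogens`` and ``acceptors`` are aligned ``(n_sites, 3)``
    arrays of candidate donor–H···acceptor contacts (Å); ``orientation`` is a
    frame label, ``"vertical"`` or ``"horizontal"``.
    """

    ring1: np.ndarray | None
    ring2: np.ndarray | None
    chain_z: np.ndarray = field(default_factory=lambda: np.empty(0))
    donors: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    hydrogens: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    acceptors: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    orientation: str = "vertical"

    def to_dict(self) -> dict:
        return {
            "ring1": None if self.ring1 is None else np.asarray(self.ring1).tolist(),
            "ring2": None if self.ring2 is None else np.asarray(self.ring2).tolist(),
            "chain_z": np.asarray(self.chain_z).tolist(),
            "donors": np.asarray(self.donors).tolist(),
            "hydrogens": np.asarray(self.hydrogens).tolist(),
            "acceptors": np.asarray(self.acceptors).tolist(),
            "orientation": self.orientation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MembraneFrame":
        arr = lambda k, shape: np.asarray(d.get(k, []), dtype=float).reshape(shape)
        return cls(
            ring1=None if d.get("ring1") is None else np.asarray(d["ring1"], float),
            ring2=None if d.get("ring2") is None else np.asarray(d["ring2"], float),
            chain_z=np.asarray(d.get("chain_z", []), dtype=float),
            donors=arr("donors", (-1, 3)),
            hydrogens=arr("hydrogens", (-1, 3)),
            acceptors=arr("acceptors", (-1, 3)),
            orientation=d.get("orientation", "vertical"),
        )


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion (closed boundaries on both cutoffs)."""

    distance_cutoff: float = 3.5  # donor–acceptor, Å
    angle_cutoff: float = 150.0  # donor–H–acceptor, deg

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class MembraneProfile:
    """Chain-atom density along the bilayer normal (midplane near z = 0)."""

    z: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.z.shape != self.density.shape or self.z.ndim != 1:
            raise ValueError("z and density must be matching 1-D arrays")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")


@dataclass
class RingDistanceSample:
    """Per-frame projected ring–ring distances with orientation labels."""

    distances: np.ndarray
    orientations: list[str]
    bin_edges: np.ndarray
    counts: np.ndarray
    mode: float
    n_skipped: int = 0


def hydrophobic_thickness(
    profile: MembraneProfile, plateau_half_width: float = 5.0
) -> float:
    """Hydrophobic core thickness D_h from a chain-atom density profile.

    The midplane is re-estimated as the density-weighted center of the
    profile (making the result invariant to rigid z-shifts).  The plateau
    level is the mean density within ``plateau_half_width`` Å of the
    midplane; scanning outward in each leaflet, D_h is the distance between
    the two half-plateau crossings (linear interpolation between grid
    points).  Invariant under any positive rescaling of the density.
    """
    z, rho = profile.z, profile.density
    total = rho.sum()
    if total <= 0:
        raise ValueError("density profile is empty")
    z_mid = float(np.sum(z * rho) / total)
    core = np.abs(z - z_mid) < plateau_half_width
    if not np.any(core) or rho[core].mean() <= 0:
        raise ValueError("no central density plateau (midplane density is zero)")
    half = 0.5 * rho[core].mean()

    def crossing(direction: int) -> float:
        """First half-plateau crossing scanning outward from the midplane."""
        order = np.argsort(direction * (z - z_mid))
        zs, rs = z[order], rho[order]
        start = np.searchsorted(direction * (zs - z_mid), 0.0)
        prev_z, prev_r = z_mid, np.interp(z_mid, z, rho)
        for zz, rr in zip(zs[start:], rs[start:]):
            if rr < half:
                if prev_r == rr:
                    return zz
                t = (half - prev_r) / (rr - prev_r)
                return prev_z + t * (zz - prev_z)
            prev_z, prev_r = zz, rr
        raise ValueError("density never falls to half the plateau in one leaflet")

    return float(abs(crossing(+1) - crossing(-1)))


def rr_distance_distribution(
    frames: Iterable[MembraneFrame],
    normal: Sequence[float] = (0.0, 0.0, 1.0),
    bin_width: float = 0.5,
) -> RingDistanceSample:
    """Distribution of the terminal-ring separation projected on the normal.

    Per frame the distance is ``|(r1 - r2) . n̂|``; frames missing a ring are
    skipped (counted in ``n_skipped``).  The histogram uses ``bin_width`` Å
    bins and the mode is the center of the most populated bin.
    """
    n_hat = np.asarray(normal, dtype=float)
    n_hat = n_hat / np.linalg.norm(n_hat)
    dists, labels, skipped = [], [], 0
    for fr in frames:
        if fr.ring1 is None or fr.ring2 is None:
            skipped += 1
            continue
        dists.append(abs(float(np.dot(np.asarray(fr.ring1) - np.asarray(fr.ring2),
                                      n_hat))))
        labels.append(fr.orientation)
    if not dists:
        raise ValueError("no frames with both rings present")
    d = np.asarray(dists)
    hi = max(d.max(), bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    mode = float(0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]))
    return RingDistanceSample(d, labels, edges, counts, mode, skipped)


def _bonds_per_frame(frame: MembraneFrame, criterion: HBondCriterion) -> int:
    d = np.asarray(frame.donors, float).reshape(-1, 3)
    h = np.asarray(frame.hydrogens, float).reshape(-1, 3)
    a = np.asarray(frame.acceptors, float).reshape(-1, 3)
    if d.size == 0:
        return 0
    da = np.linalg.norm(a - d, axis=1)
    v1, v2 = d - h, a - h
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return int(np.sum((da <= criterion.distance_cutoff)
                      & (ang >= criterion.angle_cutoff)))


def hbond_probability(
    frames: Iterable[MembraneFrame],
    criterion: HBondCriterion | None = None,
    labels: Sequence[str] | None = None,
) -> dict:
    """Mean H-bond count per frame by orientation class, and the relative loss.

    Returns ``{"vertical": ..., "horizontal": ..., "relative_loss": ...}``
    where the loss is ``1 - horizontal/vertical``; an empty class is reported
    as ``None`` (undefined, not zero) and propagates ``None`` to the loss.
    """
    criterion = criterion or HBondCriterion()
    frames = list(frames)
    if labels is None:
        labels = [fr.orientation for fr in frames]
    per_class: dict[str, list[int]] = {}
    for fr, lab in zip(frames, labels):
        per_class.setdefault(lab, []).append(_bonds_per_frame(fr, criterion))
    out: dict[str, float | None] = {
        "vertical": None,
        "horizontal": None,
        "relative_loss": None,
    }
    for lab, counts in per_class.items():
        out[lab] = float(np.mean(counts))
    v, h = out.get("vertical"), out.get("horizontal")
    if v is not None and h is not None and v > 0:
        out["relative_loss"] = 1.0 - h / v
    return out
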