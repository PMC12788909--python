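"""Atrophy evolution: concentration field, rate law, kinematic split.

Tissue loss is driven by a synthetic misfolded-protein concentration
field c that is fixed in time.  Each tissue class shrinks at a healthy
rate Gh (%/year, negative); where the local concentration exceeds a
critical threshold c_crit, the rate is accelerated by Gc through a
Heaviside gate:

    theta_dot = Gh            if c <  c_crit
    theta_dot = Gh + Gc       if c >= c_crit

The atrophy measure theta = Ja = det(Fa) starts at 1 and is integrated
with explicit Euler (exact here: the rate is constant in time because c
never changes).  Kinematically the deformation gradient splits as
F = Fe * Fa with Fa = theta^(1/3) I, so Fe = theta^(-1/3) F and
J = Je * Ja.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import LabeledHexMesh
from .regions import ALL_LABELS, BRAINSTEM_LABELS, CSF, VENTRICLE

#: default tissue-class assignment of the 17 anatomical labels.  The
#: brainstem chain is treated as white matter and the cerebellum as gray
#: matter; the deep gray nuclei count as gray matter.  All of these are
#: configurable overrides.
DEFAULT_TISSUE_CLASSES: dict[str, str] = {
    "FC": "gray", "MC": "gray", "VC": "gray", "CI": "gray", "TL": "gray",
    "NC": "gray", "Pa": "gray", "Pu": "gray", "Th": "gray", "Am": "gray",
    "CB": "gray",
    "CR": "white", "CC": "white", "M": "white", "P": "white", "Me": "white",
    "Hi": "hippocampus",
    CSF: "none", VENTRICLE: "none",
}

#: healthy and accelerated atrophy rates per tissue class, %/year
#: (negative = shrinkage)
DEFAULT_RATES: dict[str, tuple[float, float]] = {
    "gray": (-0.1, -0.2),
    "hippocampus": (-0.1, -0.2),
    "white": (-0.15, -0.35),
    "none": (0.0, 0.0),
}


@dataclass(frozen=True)
class AtrophyParams:
    """Rate table, concentration threshold, and tissue-class mapping."""

    rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATES))
    c_crit: float = 0.5
    tissue_class_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_CLASSES))

    def __post_init__(self):
        if not (0.0 <= self.c_crit <= 1.0):
            raise ValueError("c_crit must lie in [0, 1]")
        for lab in (CSF, VENTRICLE):
            if self.tissue_class_map.get(lab, "none") != "none":
                raise ValueError(f"{lab} must map to tissue class 'none'")
        for cls in set(self.tissue_class_map.values()):
            if cls not in self.rates:
                raise ValueError(f"no rate entry for tissue class {cls!r}")

    def tissue_class(self, label: str) -> str:
        try:
            return self.tissue_class_map[label]
        except KeyError:
            raise KeyError(f"no tissue class for region label {label!r}") from None


@dataclass(frozen=True)
class ConcentrationField:
    """Per-element protein concentration, affine in distance from center.

    c = 1 at the center, decreasing linearly to 0 at ``radius`` (the
    farthest mesh boundary point), clipped to [0, 1].
    """

    c: np.ndarray       # (n_elem,)
    center: np.ndarray  # (3,) mm
    radius: float       # mm

    def __post_init__(self):
        if np.any(self.c < -1e-12) or np.any(self.c > 1 + 1e-12):
            raise ValueError("concentration must lie in [0, 1]")


@dataclass
class AtrophyState:
    """Per-element atrophy measure theta = Ja and its rate."""

    theta: np.ndarray       # (n_elem,), dimensionless
    theta_dot: np.ndarray   # (n_elem,), %/year
    time: float = 0.0       # years


def build_concentration(mesh: LabeledHexMesh) -> ConcentrationField:
    """Synthetic concentration profile anchored to brainstem/hippocampus.

    The field center takes its x-coordinate from the brainstem centroid,
    its y-coordinate from the hippocampus centroid, and its z-coordinate
    from the superior extent of the hippocampal bounding box; the radius
    is the maximum distance from this center to any mesh node.
    """
    labels = mesh.element_region
    bs = np.isin(labels, BRAINSTEM_LABELS)
    hi = labels == "Hi"
    missing = [name for name, mask in
               (("brainstem (M/P/Me)", bs), ("hippocampus (Hi)", hi))
               if not mask.any()]
    if missing:
        raise ValueError(f"mesh lacks required labels: {', '.join(missing)}")

    centroids = mesh.element_centroids()
    bs_centroid = centroids[bs].mean(axis=0)
    hi_centroid = centroids[hi].mean(axis=0)
    hi_top = centroids[hi][:, 2].max()
    center = np.array([bs_centroid[0], hi_centroid[1], hi_top])

    radius = float(np.linalg.norm(mesh.node_coords - center, axis=1).max())
    dist = np.linalg.norm(centroids - center, axis=1)
    c = np.clip(1.0 - dist / radius, 0.0, 1.0)
    return ConcentrationField(c=c, center=center, radius=radius)


def atrophy_rate(c, region_label, params: AtrophyParams):
    """Threshold-gated rate theta_dot in %/year for one element.

    Returns Gh below the threshold, Gh + Gc at or above it, and 0 for
    tissue class 'none' (CSF, ventricles).
    """
    cls = params.tissue_class(region_label)
    gh, gc = params.rates[cls]
    if cls == "none":
        return 0.0
    return gh + gc if c >= params.c_crit else gh


def atrophy_rates(concentration: ConcentrationField, labels: np.ndarray,
                  params: AtrophyParams) -> np.ndarray:
    """Vectorized per-element rates (%/year) for a whole mesh."""
    gh = np.empty(labels.shape)
    gc = np.empty(labels.shape)
    for lab in np.unique(labels):
        cls = params.tissue_class(str(lab))
        sel = labels == lab
        gh[sel], gc[sel] = params.rates[cls]
    accelerated = concentration.c >= params.c_crit
    rates = gh + np.where(accelerated, gc, 0.0)
    rates[np.isin(labels, [CSF, VENTRICLE])] = 0.0
    return rates


def initial_state(n_elements: int, rates: np.ndarray) -> AtrophyState:
    return AtrophyState(theta=np.ones(n_elements), theta_dot=np.asarray(rates, float),
                        time=0.0)


def update_theta(state: AtrophyState, rates, dt: float) -> AtrophyState:
    """Explicit Euler step theta_{n+1} = theta_n + (rate/100) * dt.

    Rates are given in %/year and converted to fractions before
    integration.  Raises when any theta would drop to or below zero.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rates = np.asarray(rates, dtype=float)
    theta = state.theta + rates / 100.0 * dt
    if np.any(theta <= 0):
        raise ValueError(
            "theta would become non-positive; shorten the simulation horizon"
        )
    return AtrophyState(theta=theta, theta_dot=rates, time=state.time + dt)


def atrophy_split(F, theta):
    """Elastic part Fe = F * theta^(-1/3) of the multiplicative split.

    Satisfies Fe * Fa = F with Fa = theta^(1/3) I, and
    det(Fe) = det(F) / theta.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta must be positive")
    F = np.asarray(F, dtype=float)
    return F / theta[..., None, None] ** (1.0 / 3.0) if theta.ndim else \
        F / theta ** (1.0 / 3.0)
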