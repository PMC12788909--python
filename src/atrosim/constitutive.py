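"""One-term Ogden hyperelasticity with an atrophy-weighted energy.

The strain energy splits into an isochoric and a volumetric part,

    psi      = psi_iso + psi_vol,
    psi_iso  = (2 mu / alpha^2) (lb1^a + lb2^a + lb3^a - 3),
    psi_vol  = (kappa / 4) (J^2 - 1 - 2 ln J),

with isochoric principal stretches ``lb_a = J^(-1/3) lambda_a`` and the
bulk modulus derived from the shear modulus and the initial Poisson's
ratio, ``kappa = 2 mu (1 + nu) / (3 (1 - 2 nu))``.  Tissue loss enters
through the atrophy-weighted energy ``psi0 = Ja * psi(Fe)`` where
``Fe = theta^(-1/3) F`` is the elastic part of the multiplicative split
and ``Ja = theta``.

Stress and tangent are evaluated spectrally: with the decomposition
``F = sum_a lambda_a n_a (x) N_a`` the first Piola-Kirchhoff stress is
``P = sum_a (d psi/d lambda_a) n_a (x) N_a`` and the Cauchy stress
follows from ``sigma = J^-1 P F^T``.  Differentiating psi0 through this
relation makes Ja cancel from the Cauchy stress, which is therefore a
function of the elastic state alone — it does, however, weight the
internal-force residual through ``P0 = theta^(2/3) Pe``.

All low-level routines are vectorized over arbitrary leading batch
dimensions (shape ``(..., 3, 3)``).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .regions import CORTICAL_LABELS, CSF, NON_ANATOMICAL, VENTRICLE, scheme_groups

_EYE = np.eye(3)


class InvertedElementError(FloatingPointError):
    """A deformation gradient with non-positive determinant was met."""


def bulk_modulus(mu: float, nu: float):
    """Bulk modulus kappa = 2 mu (1+nu) / (3 (1-2 nu)) in kPa.

    Raises for nu >= 0.5 (incompressible limit has no finite kappa).
    """
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("shear modulus mu must be non-negative")
    if np.any(nu >= 0.5):
        raise ValueError("nu >= 0.5: incompressible limit, bulk modulus diverges")
    kappa = mu * 2.0 * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))
    return kappa if kappa.ndim else float(kappa)


@dataclass(frozen=True)
class MaterialParams:
    """Ogden parameters of one region: mu (kPa), alpha (-), nu (-).

    The bulk modulus is always the derived value for (mu, nu); it cannot
    be set independently.
    """

    mu: float
    alpha: float
    nu: float
    provenance: str = ""

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("nu must lie in [0, 0.5)")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")

    @property
    def kappa(self) -> float:
        return bulk_modulus(self.mu, self.nu)


@dataclass
class MaterialTable:
    """Per-region material parameters for one region scheme."""

    scheme: str
    params: dict[str, MaterialParams]
    provenance: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        required = set(scheme_groups(self.scheme)) | set(NON_ANATOMICAL)
        missing = required - set(self.params)
        if missing:
            raise ValueError(
                f"material table for scheme {self.scheme} is missing entries "
                f"for {sorted(missing)}"
            )

    def __getitem__(self, label: str) -> MaterialParams:
        try:
            return self.params[label]
        except KeyError:
            raise KeyError(f"no material entry for region {label!r}") from None

    # ---- structured-text round trip ------------------------------------
    _FIELDS = ("label", "mu_kPa", "alpha", "nu", "provenance")

    def to_csv(self, path_or_buf) -> None:
        buf = path_or_buf if hasattr(path_or_buf, "write") else open(path_or_buf, "w", newline="")
        try:
            w = csv.writer(buf)
            w.writerow(self._FIELDS)
            for label, p in self.params.items():
                w.writerow([label, repr(p.mu), repr(p.alpha), repr(p.nu), p.provenance])
        finally:
            if buf is not path_or_buf:
                buf.close()

    @classmethod
    def from_csv(cls, path_or_buf, scheme: str = "17R") -> "MaterialTable":
        buf = path_or_buf if hasattr(path_or_buf, "read") else open(path_or_buf, newline="")
        try:
            rows = list(csv.reader(buf))
        finally:
            if buf is not path_or_buf:
                buf.close()
        if rows[0] != list(cls._FIELDS):
            raise ValueError(f"bad material file header {rows[0]!r}")
        params = {}
        for label, mu, alpha, nu, prov in rows[1:]:
            params[label] = MaterialParams(float(mu), float(alpha), float(nu), prov)
        return cls(scheme=scheme, params=params)


def default_material_table() -> MaterialTable:
    """The shipped 17R table (placeholder values of physiological magnitude).

    mu is of order 1 kPa and alpha strongly negative, the regime reported
    for brain tissue; the CSF shell is ten times softer than the mean
    cortical stiffness and more compressible (nu = 0.3), the ventricles
    carry the same ultrasoft CSF-like material.  Every value is meant to
    be edited: the table round-trips losslessly through CSV.
    """
    with resources.files("atrosim").joinpath("data/materials_17R.csv").open() as fh:
        return MaterialTable.from_csv(fh, scheme="17R")


# =====================================================================
# spectral kinematics
# =====================================================================

def _det33(F):
    return (
        F[..., 0, 0] * (F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1])
        - F[..., 0, 1] * (F[..., 1, 0] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 0])
        + F[..., 0, 2] * (F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0])
    )


def spectral_decomposition(F):
    """Principal stretches and directions of F (descending order).

    Returns ``(lam, n, N)`` with ``F = sum_a lam_a n[:, a] (x) N[:, a]``;
    ``lam`` has shape (..., 3), ``n``/``N`` are column matrices.
    """
    F = np.asarray(F, dtype=float)
    J = _det33(F)
    if np.any(J <= 0):
        raise InvertedElementError("det(F) <= 0: inverted deformation state")
    C = np.swapaxes(F, -1, -2) @ F
    w, N = np.linalg.eigh(C)          # ascending eigenvalues of C
    w = w[..., ::-1]
    N = N[..., ::-1]
    lam = np.sqrt(np.maximum(w, 0.0))
    n = (F @ N) / lam[..., None, :]
    return lam, n, N


def isochoric_stretches(F):
    """Isochoric principal stretches ``J^(-1/3) lambda_a``, descending.

    Their product is 1: a pure dilatation has no isochoric part.
    """
    lam, _, _ = spectral_decomposition(F)
    J = np.prod(lam, axis=-1, keepdims=True)
    return lam * J ** (-1.0 / 3.0)


# =====================================================================
# energy and its stretch derivatives
# =====================================================================

def _psi_parts(lam, mu, alpha, kappa):
    """psi_iso, psi_vol for principal stretches lam (..., 3)."""
    J = np.prod(lam, axis=-1)
    lb = lam * J[..., None] ** (-1.0 / 3.0)
    S = np.sum(lb**alpha[..., None], axis=-1)
    psi_iso = 2.0 * mu / alpha**2 * (S - 3.0)
    psi_vol = kappa / 4.0 * (J**2 - 1.0 - 2.0 * np.log(J))
    return psi_iso, psi_vol


def _psi_derivs(lam, mu, alpha, kappa):
    """First and second derivatives of psi with respect to the stretches.

    Returns ``(psi_a, psi_ab)`` of shapes (..., 3) and (..., 3, 3).
    """
    J = np.prod(lam, axis=-1)[..., None]
    lb_a = (lam * J ** (-1.0 / 3.0)) ** alpha[..., None]   # lb^alpha, (...,3)
    S = np.sum(lb_a, axis=-1)[..., None]
    mu_ = mu[..., None]
    al = alpha[..., None]
    ka = kappa[..., None]

    psi_a = 2.0 * mu_ / al * (lb_a - S / 3.0) / lam
    psi_a = psi_a + ka / 2.0 * (J**2 - 1.0) / lam

    # second derivatives
    lam_a = lam[..., :, None]
    lam_c = lam[..., None, :]
    lb_aa = lb_a[..., :, None]
    lb_cc = lb_a[..., None, :]
    S2 = S[..., None]
    mu2 = mu[..., None, None]
    al2 = alpha[..., None, None]
    ka2 = kappa[..., None, None]
    J2 = J[..., None] ** 2
    delta = _EYE

    psi_ab = 2.0 * mu2 / al2 * (
        -delta * (lb_aa - S2 / 3.0) / lam_a**2
        + al2 / (lam_a * lam_c) * (lb_aa * (delta - 1.0 / 3.0) - lb_cc / 3.0 + S2 / 9.0)
    )
    psi_ab = psi_ab + ka2 / 2.0 * (2.0 * J2 / (lam_a * lam_c) - delta * (J2 - 1.0) / lam_a**2)
    return psi_a, psi_ab


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy densities in kPa: isochoric, volumetric, total, atrophy-weighted."""

    psi_iso: float
    psi_vol: float
    psi: float
    psi0: float


def strain_energy(F, p: MaterialParams, Ja: float = 1.0) -> EnergyBreakdown:
    """Ogden strain-energy breakdown at deformation gradient F.

    ``psi0 = Ja * psi`` is the atrophy-weighted density per unit
    original reference volume.
    """
    if Ja <= 0:
        raise ValueError("Ja must be positive")
    lam, _, _ = spectral_decomposition(np.asarray(F, dtype=float))
    psi_iso, psi_vol = _psi_parts(
        lam, np.asarray(p.mu, float), np.asarray(p.alpha, float), np.asarray(p.kappa, float)
    )
    psi = float(psi_iso + psi_vol)
    return EnergyBreakdown(float(psi_iso), float(psi_vol), psi, Ja * psi)


# =====================================================================
# stress and tangent (batch form used by the FEM assembly)
# =====================================================================

def _pk1_from_spectral(lam, n, N, psi_a):
    return np.einsum("...a,...ia,...Ja->...iJ", psi_a, n, N, optimize=True)


def _tangent_from_spectral(lam, n, N, psi_a, psi_ab):
    """dP/dF for an isotropic stretch-based energy (spectral formula).

    Off-diagonal shear coefficients use the l'Hopital limit when two
    stretches coincide (relative gap below 1e-6).
    """
    A = np.einsum("...ab,...ia,...Ja,...kb,...Lb->...iJkL", psi_ab, n, N, n, N,
                  optimize=True)

    lam_a = lam[..., :, None]
    lam_b = lam[..., None, :]
    denom = lam_a**2 - lam_b**2
    gap_ok = np.abs(denom) > 1e-6 * (lam_a**2 + lam_b**2)
    safe = np.where(gap_ok, denom, 1.0)
    pa = psi_a[..., :, None]
    pb = psi_a[..., None, :]

    c1 = (pa * lam_a - pb * lam_b) / safe
    c2 = (pa * lam_b - pb * lam_a) / safe
    # coincident-stretch limits (l'Hopital in lam_b -> lam_a)
    diag = np.einsum("...aa->...a", psi_ab)
    paa = diag[..., :, None]
    pab = psi_ab
    c1_lim = 0.5 * (paa - pab) + pa / (lam_a + lam_b)
    c2_lim = 0.5 * (paa - pab) - pa / (lam_a + lam_b)
    c1 = np.where(gap_ok, c1, c1_lim)
    c2 = np.where(gap_ok, c2, c2_lim)
    off = ~np.eye(3, dtype=bool)
    c1 = c1 * off
    c2 = c2 * off

    A = A + np.einsum("...ab,...ia,...Jb,...ka,...Lb->...iJkL", c1, n, N, n, N,
                      optimize=True)
    A = A + np.einsum("...ab,...ia,...Jb,...kb,...La->...iJkL", c2, n, N, n, N,
                      optimize=True)
    return A


def ogden_pk1(F, mu, alpha, kappa, theta=1.0, tangent=False):
    """Atrophy-weighted first Piola-Kirchhoff stress (and tangent).

    ``P0 = d(theta * psi(Fe))/dF`` with ``Fe = theta^(-1/3) F``; the
    optional tangent is ``A0 = dP0/dF``.  All arguments broadcast over
    leading batch dimensions.
    """
    F = np.asarray(F, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, float), F.shape[:-2]).copy()
    alpha = np.broadcast_to(np.asarray(alpha, float), F.shape[:-2]).copy()
    kappa = np.broadcast_to(np.asarray(kappa, float), F.shape[:-2]).copy()
    theta = np.broadcast_to(np.asarray(theta, float), F.shape[:-2])

    t13 = theta ** (1.0 / 3.0)
    Fe = F / t13[..., None, None]
    lam, n, N = spectral_decomposition(Fe)
    psi_a, psi_ab = _psi_derivs(lam, mu, alpha, kappa)
    Pe = _pk1_from_spectral(lam, n, N, psi_a)
    P0 = theta[..., None, None] ** (2.0 / 3.0) * Pe
    if not tangent:
        return P0
    Ae = _tangent_from_spectral(lam, n, N, psi_a, psi_ab)
    A0 = t13[..., None, None, None, None] * Ae
    return P0, A0


def ogden_energy_density(F, mu, alpha, kappa, theta=1.0):
    """Atrophy-weighted energy density ``theta * psi(Fe)`` (batch)."""
    F = np.asarray(F, dtype=float)
    theta = np.broadcast_to(np.asarray(theta, float), F.shape[:-2])
    Fe = F / theta[..., None, None] ** (1.0 / 3.0)
    lam, _, _ = spectral_decomposition(Fe)
    mu = np.broadcast_to(np.asarray(mu, float), F.shape[:-2])
    alpha = np.broadcast_to(np.asarray(alpha, float), F.shape[:-2])
    kappa = np.broadcast_to(np.asarray(kappa, float), F.shape[:-2])
    psi_iso, psi_vol = _psi_parts(lam, mu, alpha, kappa)
    return theta * (psi_iso + psi_vol)


def cauchy_stress(Fe, p: MaterialParams, Ja: float = 1.0):
    """Cauchy stress (kPa) of the elastic state Fe.

    ``sigma = Je^-1 (d psi/d Fe) Fe^T``; symmetric, zero at Fe = I, and
    independent of Ja (the atrophy weight cancels when psi0 = Ja psi is
    pushed forward to the current configuration).
    """
    if Ja <= 0:
        raise ValueError("Ja must be positive")
    Fe = np.asarray(Fe, dtype=float)
    lam, n, N = spectral_decomposition(Fe)
    mu = np.broadcast_to(np.asarray(p.mu, float), Fe.shape[:-2])
    alpha = np.broadcast_to(np.asarray(p.alpha, float), Fe.shape[:-2])
    kappa = np.broadcast_to(np.asarray(p.kappa, float), Fe.shape[:-2])
    psi_a, _ = _psi_derivs(lam, mu, alpha, kappa)
    Je = np.prod(lam, axis=-1)
    beta = lam * psi_a / Je[..., None]
    sigma = np.einsum("...a,...ia,...ja->...ij", beta, n, n, optimize=True)
    return 0.5 * (sigma + np.swapaxes(sigma, -1, -2))


def cauchy_stress_batch(Fe, mu, alpha, kappa):
    """Vectorized Cauchy stress for per-point parameter arrays."""
    Fe = np.asarray(Fe, dtype=float)
    lam, n, N = spectral_decomposition(Fe)
    mu = np.broadcast_to(np.asarray(mu, float), Fe.shape[:-2]).copy()
    alpha = np.broadcast_to(np.asarray(alpha, float), Fe.shape[:-2]).copy()
    kappa = np.broadcast_to(np.asarray(kappa, float), Fe.shape[:-2]).copy()
    psi_a, _ = _psi_derivs(lam, mu, alpha, kappa)
    Je = np.prod(lam, axis=-1)
    beta = lam * psi_a / Je[..., None]
    sigma = np.einsum("...a,...ia,...ja->...ij", beta, n, n, optimize=True)
    return 0.5 * (sigma + np.swapaxes(sigma, -1, -2))


def material_tangent(Fe, p: MaterialParams, Ja: float = 1.0):
    """Fourth-order tangent ``d^2(Ja psi)/dF dF`` at elastic state Fe.

    At Fe = I (and Ja = 1) this is the small-strain isotropic elasticity
    tensor with Lame moduli ``(kappa - 2 mu / 3, mu)``.
    """
    if Ja <= 0:
        raise ValueError("Ja must be positive")
    Fe = np.asarray(Fe, dtype=float)
    shape = Fe.shape[:-2]
    mu = np.broadcast_to(np.asarray(p.mu, float), shape).copy()
    alpha = np.broadcast_to(np.asarray(p.alpha, float), shape).copy()
    kappa = np.broadcast_to(np.asarray(p.kappa, float), shape).copy()
    lam, n, N = spectral_decomposition(Fe)
    psi_a, psi_ab = _psi_derivs(lam, mu, alpha, kappa)
    Ae = _tangent_from_spectral(lam, n, N, psi_a, psi_ab)
    return Ja ** (1.0 / 3.0) * Ae
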