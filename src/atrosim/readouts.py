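"""Mechanical readouts and regional volume summaries.

Five fields characterize the tissue response: displacement magnitude
(mm), principal stretches (square roots of the eigenvalues of the left
Cauchy-Green tensor b = F F^T), maximum shear gamma_max = lambda1 -
lambda3, hydrostatic stress sigma_hyd = tr(sigma)/3 (negative =
compression), and von Mises stress sigma_VM = sqrt(3/2 s:s) of the
deviatoric stress s.  Fields are evaluated per element from
quadrature-averaged F and sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import LabeledHexMesh
from .regions import CSF, VENTRICLE

_SYM_TOL = 1e-8


def principal_stretches(F):
    """Principal stretches (descending) from F via eigenvalues of b = F F^T."""
    F = np.asarray(F, dtype=float)
    det = np.linalg.det(F)
    if np.any(det <= 0):
        raise ValueError("det(F) <= 0: degenerate deformation gradient")
    b = F @ np.swapaxes(F, -1, -2)
    w = np.linalg.eigvalsh(b)          # ascending
    lam = np.sqrt(np.maximum(w[..., ::-1], 0.0))
    return lam


def max_shear(lam):
    """Maximum shear gamma_max = lambda_1 - lambda_3 of a sorted triple."""
    lam = np.asarray(lam, dtype=float)
    return lam[..., 0] - lam[..., -1]


def stress_readouts(sigma):
    """Hydrostatic and von Mises stress of a symmetric Cauchy tensor.

    Raises for input asymmetric beyond tolerance.
    """
    sigma = np.asarray(sigma, dtype=float)
    asym = np.abs(sigma - np.swapaxes(sigma, -1, -2)).max()
    scale = max(np.abs(sigma).max(), 1.0)
    if asym > 1e-8 * scale:
        raise ValueError(f"stress tensor asymmetric beyond tolerance ({asym:g})")
    hyd = np.trace(sigma, axis1=-2, axis2=-1) / 3.0
    s = sigma - hyd[..., None, None] * np.eye(3)
    vm = np.sqrt(1.5 * np.sum(s * s, axis=(-2, -1)))
    return hyd, vm


@dataclass
class ReadoutFields:
    """Per-element readouts of one converged increment."""

    displacement: np.ndarray   # |u| at element centroid, mm
    stretches: np.ndarray      # (n_elem, 3), descending
    max_shear: np.ndarray      # lambda1 - lambda3
    sigma_hyd: np.ndarray      # kPa
    sigma_vm: np.ndarray       # kPa

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "displacement": self.displacement,
            "lambda1": self.stretches[:, 0],
            "lambda2": self.stretches[:, 1],
            "lambda3": self.stretches[:, 2],
            "max_shear": self.max_shear,
            "sigma_hyd": self.sigma_hyd,
            "sigma_vm": self.sigma_vm,
        }


def compute_readouts(mesh: LabeledHexMesh, u: np.ndarray, F_elem: np.ndarray,
                     sigma_elem: np.ndarray) -> ReadoutFields:
    """Element-level readouts from nodal displacements and averaged tensors."""
    u_elem = u[mesh.element_connectivity].mean(axis=1)
    lam = principal_stretches(F_elem)
    hyd, vm = stress_readouts(sigma_elem)
    return ReadoutFields(
        displacement=np.linalg.norm(u_elem, axis=1),
        stretches=lam,
        max_shear=max_shear(lam),
        sigma_hyd=hyd,
        sigma_vm=vm,
    )


def region_summary(mesh: LabeledHexMesh, J_elem: np.ndarray,
                   readouts: ReadoutFields | None = None,
                   denominator: str = "brain") -> pd.DataFrame:
    """Per-region volumes, fractions, and readout means.

    Deformed region volume integrates J over the region's elements.
    ``denominator`` selects the volume-fraction reference set: "brain"
    (anatomical tissue + ventricles, excluding the outer CSF shell — the
    default) or "all".  Percentage change is (deformed - undeformed) /
    undeformed x 100; the volume-fraction change convention is initial -
    final.  Means are volume-weighted (undeformed element volumes, which
    coincide with count weighting on a voxel mesh).
    """
    if denominator not in ("brain", "all"):
        raise ValueError("denominator must be 'brain' or 'all'")
    v0 = mesh.element_volumes()
    v_def = v0 * J_elem
    labels = mesh.element_region
    denom_mask = np.ones(mesh.n_elements, bool) if denominator == "all" \
        else labels != CSF
    denom_v0 = v0[denom_mask].sum()
    denom_vdef = v_def[denom_mask].sum()

    rows = []
    for lab in np.unique(labels):
        sel = labels == lab
        und = v0[sel].sum()
        de = v_def[sel].sum()
        row = {
            "region": str(lab),
            "n_elements": int(sel.sum()),
            "undeformed_volume_mm3": und,
            "deformed_volume_mm3": de,
            "volume_change_pct": (de - und) / und * 100.0,
            "volume_fraction": (de / denom_vdef) if (lab != CSF or denominator == "all") else np.nan,
            "initial_volume_fraction": (und / denom_v0) if (lab != CSF or denominator == "all") else np.nan,
        }
        if readouts is not None:
            w = v0[sel]
            for name, vals in readouts.as_dict().items():
                row[f"mean_{name}"] = float(np.average(vals[sel], weights=w))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("region")
    df["volume_fraction_change"] = df["initial_volume_fraction"] - df["volume_fraction"]
    return df
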