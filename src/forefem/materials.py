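"""Constitutive models for the forefoot model regions.

Three material classes cover the whole model:

* one-term Ogden hyperelasticity for the (near-incompressible) skin and bulk
  soft tissue, written with the ``mu/alpha`` prefactor convention,
  ``W = (mu/alpha) (lam1^a + lam2^a + lam3^a - 3)``, plus a volumetric
  penalty that enforces incompressibility numerically;
* the Storakers strain energy for the highly compressible orthosis and
  shoe-sole foams;
* linear elasticity (as a St. Venant-Kirchhoff law, so it remains objective
  under the finite-strain solver) for the shoe upper, sock and bone.

All stresses are in kPa and lengths in mm.  Every model exposes its strain
energy and its first/second derivatives with respect to the principal
stretches; the generic routines below turn those into the second
Piola-Kirchhoff stress and the material tangent in the principal basis of
``C = F^T F``, which is what the total-Lagrangian solver consumes.

The closed-form uniaxial responses (traction-free lateral faces) are kept on
the classes as independent oracles for the finite-element path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml


class MaterialDomainError(ValueError):
    """Raised for non-physical kinematic input (non-positive stretch or J)."""


class ElementInversionError(RuntimeError):
    """det F <= 0 at a quadrature point; carries the offending element id."""

    def __init__(self, message: str, element_id: Optional[int] = None):
        super().__init__(message)
        self.element_id = element_id


# ---------------------------------------------------------------------------
# material classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OgdenParams:
    """One-term Ogden solid with a volumetric penalty.

    Parameters
    ----------
    mu : float
        Shear-like modulus of the power term, kPa.  With the default
        ``prefactor='paper'`` convention the deviatoric energy is
        ``(mu/alpha) * (sum lam_i^alpha - 3)`` and the initial shear modulus
        is ``mu * alpha / 2``.
    alpha : float
        Deviatoric exponent (nonzero).
    kappa_factor : float
        Bulk penalty ``K = kappa_factor * mu``; the default 1000 keeps the
        volumetric strain three orders of magnitude below the deviatoric one,
        emulating incompressibility.
    prefactor : str
        ``'paper'`` for the ``mu/alpha`` prefactor, ``'standard'`` for the
        ``2 mu / alpha^2`` convention used by several FE codes.
    """

    mu: float
    alpha: float
    kappa_factor: float = 1000.0
    prefactor: str = "paper"

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError(f"Ogden mu must be > 0, got {self.mu}")
        if self.alpha == 0:
            raise ValueError("Ogden alpha must be nonzero")
        if self.prefactor not in ("paper", "standard"):
            raise ValueError(f"unknown prefactor convention {self.prefactor!r}")

    # s * mu * (sum lam^a - 3) with s depending on the convention
    @property
    def _s(self) -> float:
        return 1.0 / self.alpha if self.prefactor == "paper" else 2.0 / self.alpha**2

    @property
    def shear_modulus_initial(self) -> float:
        """Small-strain shear modulus implied by the power term (kPa)."""
        return 0.5 * self._s * self.mu * self.alpha**2

    @property
    def bulk_penalty(self) -> float:
        return self.kappa_factor * self.mu

    def energy(self, lam: np.ndarray, J: np.ndarray) -> np.ndarray:
        s, mu, a, K = self._s, self.mu, self.alpha, self.bulk_penalty
        c = s * mu * a  # compensating pressure so the reference state is stress-free
        return (s * mu * (np.sum(lam**a, axis=-1) - 3.0)
                - c * np.log(J) + 0.5 * K * (J - 1.0) ** 2)

    def dW(self, lam: np.ndarray) -> np.ndarray:
        s, mu, a, K = self._s, self.mu, self.alpha, self.bulk_penalty
        c = s * mu * a
        J = np.prod(lam, axis=-1, keepdims=True)
        return (s * mu * a * lam ** (a - 1.0) - c / lam
                + K * (J - 1.0) * J / lam)

    def d2W(self, lam: np.ndarray) -> np.ndarray:
        s, mu, a, K = self._s, self.mu, self.alpha, self.bulk_penalty
        c = s * mu * a
        J1 = np.prod(lam, axis=-1)[..., None]
        J = J1[..., None]
        li = lam[..., :, None]
        lj = lam[..., None, :]
        eye = np.eye(3)
        diag = (s * mu * a * (a - 1.0) * lam ** (a - 2.0) + c / lam**2
                - K * (J1 - 1.0) * J1 / lam**2)
        return K * J * (2.0 * J - 1.0) / (li * lj) + eye * diag[..., :, None]

    def uniaxial_cauchy(self, stretch: float) -> float:
        """Closed-form uniaxial Cauchy stress in the incompressible limit (kPa)."""
        if stretch <= 0:
            raise MaterialDomainError(f"stretch must be > 0, got {stretch}")
        s, mu, a = self._s, self.mu, self.alpha
        return s * a * mu * (stretch**a - stretch ** (-a / 2.0))


@dataclass(frozen=True)
class StorakersParams:
    """Storakers strain energy for highly compressible foam.

    ``W = (2 mu / alpha^2) (sum lam_i^alpha - 3 + (J^(-alpha beta) - 1)/beta)``.
    ``beta`` is the volumetric exponent; effective Poisson's ratio is
    ``beta / (1 + 2 beta)``.
    """

    mu: float
    alpha: float
    beta: float
    #: reproduce a variant with "-3" in place of "-1" in the volumetric term
    #: (energy shifted by a constant; the stress is identical).
    printed_volumetric_term: bool = False

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError(f"Storakers mu must be > 0, got {self.mu}")
        if self.beta <= 0:
            raise ValueError(f"Storakers beta must be > 0, got {self.beta}")
        if self.alpha == 0:
            raise ValueError("Storakers alpha must be nonzero")

    def energy(self, lam: np.ndarray, J: np.ndarray) -> np.ndarray:
        mu, a, b = self.mu, self.alpha, self.beta
        ref = 3.0 if self.printed_volumetric_term else 1.0
        return (2.0 * mu / a**2) * (np.sum(lam**a, axis=-1) - 3.0
                                    + (J ** (-a * b) - ref) / b)

    def dW(self, lam: np.ndarray) -> np.ndarray:
        mu, a, b = self.mu, self.alpha, self.beta
        J = np.prod(lam, axis=-1, keepdims=True)
        return (2.0 * mu / a) * (lam ** (a - 1.0) - J ** (-a * b) / lam)

    def d2W(self, lam: np.ndarray) -> np.ndarray:
        mu, a, b = self.mu, self.alpha, self.beta
        J = np.prod(lam, axis=-1)[..., None, None]
        li = lam[..., :, None]
        lj = lam[..., None, :]
        eye = np.eye(3)
        diag = ((a - 1.0) * lam ** (a - 2.0)
                + (np.prod(lam, axis=-1)[..., None]) ** (-a * b) / lam**2)
        return (2.0 * mu / a) * (a * b * J ** (-a * b) / (li * lj)
                                 + eye * diag[..., :, None])

    def uniaxial_cauchy(self, stretch: float) -> float:
        """Uniaxial Cauchy stress with traction-free lateral faces (kPa).

        Lateral equilibrium gives ``lam_t = lam^(-beta/(1+2 beta))`` and
        ``J = lam^(1/(1+2 beta))``; the axial Kirchhoff stress is
        ``(2 mu/alpha)(lam^alpha - J^(-alpha beta))``.
        """
        if stretch <= 0:
            raise MaterialDomainError(f"stretch must be > 0, got {stretch}")
        mu, a, b = self.mu, self.alpha, self.beta
        J = stretch ** (1.0 / (1.0 + 2.0 * b))
        tau = (2.0 * mu / a) * (stretch**a - J ** (-a * b))
        return tau / J


@dataclass(frozen=True)
class LinearParams:
    """Linear elastic material (E in MPa), evaluated as St. Venant-Kirchhoff.

    The quadratic-in-Green-strain form keeps the response objective inside
    the finite-strain solver while reducing to Hooke's law for small strain.
    """

    E: float
    nu: float

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError(f"Young's modulus must be > 0, got {self.E}")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError(f"Poisson's ratio must lie in (-1, 0.5), got {self.nu}")

    @property
    def _lame(self) -> tuple[float, float]:
        E_kpa = self.E * 1000.0  # MPa -> kPa
        lam = E_kpa * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))
        mu = E_kpa / (2.0 * (1.0 + self.nu))
        return lam, mu

    def energy(self, lam: np.ndarray, J: np.ndarray) -> np.ndarray:
        lame_l, lame_m = self._lame
        e = 0.5 * (lam**2 - 1.0)
        tr = np.sum(e, axis=-1)
        return 0.5 * lame_l * tr**2 + lame_m * np.sum(e**2, axis=-1)

    def dW(self, lam: np.ndarray) -> np.ndarray:
        lame_l, lame_m = self._lame
        e = 0.5 * (lam**2 - 1.0)
        tr = np.sum(e, axis=-1, keepdims=True)
        return (lame_l * tr + 2.0 * lame_m * e) * lam

    def d2W(self, lam: np.ndarray) -> np.ndarray:
        lame_l, lame_m = self._lame
        e = 0.5 * (lam**2 - 1.0)
        tr = np.sum(e, axis=-1)[..., None]
        li = lam[..., :, None]
        lj = lam[..., None, :]
        eye = np.eye(3)
        diag = 2.0 * lame_m * lam**2 + lame_l * tr + 2.0 * lame_m * e
        return lame_l * li * lj + eye * diag[..., :, None]

    def uniaxial_cauchy(self, stretch: float) -> float:
        if stretch <= 0:
            raise MaterialDomainError(f"stretch must be > 0, got {stretch}")
        lame_l, lame_m = self._lame
        e_ax = 0.5 * (stretch**2 - 1.0)
        e_t = -lame_l * e_ax / (2.0 * (lame_l + lame_m))
        lam_t = np.sqrt(2.0 * e_t + 1.0)
        S_ax = lame_l * (e_ax + 2.0 * e_t) + 2.0 * lame_m * e_ax
        J = stretch * lam_t**2
        return float(stretch**2 * S_ax / J)


Material = OgdenParams | StorakersParams | LinearParams


# ---------------------------------------------------------------------------
# generic evaluation in the principal basis
# ---------------------------------------------------------------------------

def strain_energy(material: Material, stretches, J=None):
    """Strain energy density (kPa) at the given principal stretches.

    ``J`` defaults to the product of the stretches; for the compressible
    models it may be supplied independently (elastic volume ratio).
    """
    lam = np.asarray(stretches, dtype=float)
    if np.any(lam <= 0):
        raise MaterialDomainError("principal stretches must be > 0")
    if J is None:
        J = np.prod(lam, axis=-1)
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise MaterialDomainError("volume ratio J must be > 0")
    return material.energy(lam, J)


def principal_stress_and_moduli(material: Material, lam: np.ndarray):
    """Principal 2nd Piola-Kirchhoff stresses and their stretch derivatives.

    Returns ``(S_a, dSa_dlb)`` with ``S_a = (1/lam_a) dW/dlam_a`` and the
    full 3x3 derivative matrix, batched over leading axes of ``lam``.
    """
    w1 = material.dW(lam)
    w2 = material.d2W(lam)
    S = w1 / lam
    eye = np.eye(3)
    dS = w2 / lam[..., :, None] - eye * (w1 / lam**2)[..., :, None]
    return S, dS


def stress_and_tangent(material: Material, F: np.ndarray, element_id=None):
    """Second Piola-Kirchhoff stress and material tangent dS/dE.

    ``F`` may be batched ``(..., 3, 3)``.  The tangent is returned as a full
    ``(..., 3, 3, 3, 3)`` tensor with both minor symmetries.  Raises
    :class:`ElementInversionError` if any ``det F <= 0``.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        bad = element_id
        if bad is None and J.ndim > 0:
            bad = int(np.argmin(J))
        raise ElementInversionError(
            f"non-positive det(F) encountered (min J = {np.min(J):.3e})", bad)

    C = np.einsum("...ki,...kj->...ij", F, F)
    lam2, N = np.linalg.eigh(C)            # ascending; N columns are directions
    lam2 = np.maximum(lam2, 1e-30)
    lam = np.sqrt(lam2)

    S_p, dS = principal_stress_and_moduli(material, lam)

    # assemble the tangent core in the principal (eigen)basis, then rotate:
    # D_aabb = (1/lam_b) dS_a/dlam_b ;  D_abab = D_abba = g_ab (a != b)
    c_ab = dS / lam[..., None, :]
    shape = lam.shape[:-1]
    D = np.zeros(shape + (3, 3, 3, 3))
    idx = np.arange(3)
    D[..., idx[:, None], idx[:, None], idx[None, :], idx[None, :]] = c_ab
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            d2 = lam2[..., b] - lam2[..., a]
            near = np.abs(d2) < 1e-9 * np.maximum(lam2[..., a], lam2[..., b])
            with np.errstate(divide="ignore", invalid="ignore"):
                g = (S_p[..., b] - S_p[..., a]) / d2
            g_lim = (dS[..., a, a] - dS[..., a, b]) / (2.0 * lam[..., b])
            g = np.where(near, g_lim, g)
            D[..., a, b, a, b] = g
            D[..., a, b, b, a] = g
    S = np.einsum("...a,...ia,...ja->...ij", S_p, N, N, optimize=True)
    CC = np.einsum("...ip,...jq,...kr,...ls,...pqrs->...ijkl",
                   N, N, N, N, D, optimize=True)
    return S, CC


def analytic_uniaxial(material: Material, stretch: float) -> float:
    """Closed-form uniaxial Cauchy stress (kPa) with free lateral faces."""
    return material.uniaxial_cauchy(stretch)


# ---------------------------------------------------------------------------
# material library
# ---------------------------------------------------------------------------

_TABLE_DEFAULTS = {
    "upper": LinearParams(E=200.0, nu=0.3),
    "sock": LinearParams(E=1.8, nu=0.4),
    "bone": LinearParams(E=7300.0, nu=0.3),
    "skin": OgdenParams(mu=452.0, alpha=5.6),
    "soft_tissue": OgdenParams(mu=36.0, alpha=4.5),
    "orthosis": StorakersParams(mu=144.0, alpha=4.013, beta=0.057),
    "sole": StorakersParams(mu=1588.0, alpha=7.708, beta=0.292),
}


@dataclass
class MaterialLibrary:
    """Region-name -> material mapping with the standard defaults built in."""

    materials: dict = field(default_factory=lambda: dict(_TABLE_DEFAULTS))

    @classmethod
    def defaults(cls) -> "MaterialLibrary":
        return cls()

    def __getitem__(self, region: str) -> Material:
        try:
            return self.materials[region]
        except KeyError:
            raise KeyError(f"no material assigned to region {region!r}") from None

    def __contains__(self, region: str) -> bool:
        return region in self.materials

    def validate_regions(self, regions) -> None:
        missing = [r for r in regions if r not in self.materials]
        if missing:
            raise KeyError(f"regions without a material entry: {missing}")

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {}
        for region, mat in self.materials.items():
            if isinstance(mat, OgdenParams):
                doc[region] = {"model": "ogden", "mu": mat.mu, "alpha": mat.alpha,
                               "kappa_factor": mat.kappa_factor,
                               "prefactor": mat.prefactor}
            elif isinstance(mat, StorakersParams):
                doc[region] = {"model": "storakers", "mu": mat.mu,
                               "alpha": mat.alpha, "beta": mat.beta}
            else:
                doc[region] = {"model": "linear", "E": mat.E, "nu": mat.nu}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "MaterialLibrary":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        mats = {}
        for region, entry in doc.items():
            model = entry.pop("model")
            if model == "ogden":
                mats[region] = OgdenParams(**entry)
            elif model == "storakers":
                mats[region] = StorakersParams(**entry)
            elif model == "linear":
                mats[region] = LinearParams(**entry)
            else:
                raise ValueError(f"unknown material model {model!r} for {region}")
        return cls(mats)
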