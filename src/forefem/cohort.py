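"""Synthetic cohort generation with controllable covariate structure.

A :class:`CohortSpec` describes the marginal distributions of the clinical
covariates (BMI, body mass, disease duration, LFIS-IF impairment score,
instances of bursae/erosion/hypertrophy) and of the geometric parameters
(tissue depth under MH1, sesamoid offset fraction, MH1 medial-plantar
curvature), together with target rank correlations among them.  Samples are
drawn through a Gaussian copula: a multivariate normal with correlation
``2 sin(pi rho_s / 6)`` (so the *rank* correlation of the copula matches the
target), pushed through the marginal quantile functions.

The defaults emulate the covariate structure observed in small RA forefoot
cohorts: disease duration correlates positively with sesamoid offset
(rho ~ 0.7) and negatively with tissue depth under MH1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .phantom import PhantomSpec


class CorrelationError(ValueError):
    """Target rank-correlation matrix is not positive semi-definite."""


@dataclass
class ClinicalRecord:
    """Per-subject clinical covariates carried alongside the model outputs."""

    bmi: float
    disease_duration: float      # years
    lfis_if: float               # 0-21
    instances_count: float       # bursae+erosion+hypertrophy, 0-19

    @property
    def bmi_group(self) -> str:
        return "normal" if 18.5 <= self.bmi < 25.0 else "high"


#: marginal specifications: name -> (scipy.stats frozen distribution, clip range)
def _default_marginals():
    return {
        "bmi": (stats.truncnorm(-2.2, 3.0, loc=25.6, scale=3.2), None),
        "height": (stats.norm(loc=1.62, scale=0.055), (1.45, 1.85)),
        "disease_duration": (stats.lognorm(s=0.9, scale=9.0), (1.0, 45.0)),
        "lfis_if": (stats.truncnorm(-1.8, 1.3, loc=11.0, scale=5.5), (0.0, 21.0)),
        "instances_count": (stats.truncnorm(-1.4, 2.8, loc=5.0, scale=3.5), (0.0, 19.0)),
        "tissue_depth_mh1": (stats.norm(loc=15.6, scale=2.6), (9.0, 22.0)),
        "sesamoid_offset_frac": (stats.norm(loc=0.24, scale=0.12), (0.0, 1.4)),
        "mh1_curvature": (stats.norm(loc=0.145, scale=0.02), (0.08, 0.168)),
    }


def _default_rank_targets():
    # duration <-> offset and offset <-> depth as observed; the implied
    # duration <-> depth entry keeps the matrix positive definite
    return {
        ("disease_duration", "sesamoid_offset_frac"): 0.698,
        ("sesamoid_offset_frac", "tissue_depth_mh1"): -0.721,
        ("disease_duration", "tissue_depth_mh1"): -0.503,
    }


@dataclass
class CohortSpec:
    """Sampling plan for a synthetic cohort.

    ``rank_targets`` maps variable-name pairs to target Spearman
    correlations; unspecified pairs are independent.  ``template`` is the
    geometric phantom all subjects are derived from (per-subject geometry
    parameters override its fields; its scale sets the cohort's anatomy
    scale, which keeps reduced-scale test cohorts cheap).
    """

    n_subjects: int = 13
    marginals: dict = field(default_factory=_default_marginals)
    rank_targets: dict = field(default_factory=_default_rank_targets)
    template: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")


def _copula_correlation(spec: CohortSpec, names):
    n = len(names)
    C = np.eye(n)
    for (a, b), rho in spec.rank_targets.items():
        if a not in names or b not in names:
            raise KeyError(f"rank target references unknown variable {(a, b)}")
        ia, ib = names.index(a), names.index(b)
        r = 2.0 * np.sin(np.pi * rho / 6.0)   # rank -> normal-score correlation
        C[ia, ib] = C[ib, ia] = r
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-10:
        raise CorrelationError(
            f"target rank-correlation matrix is not positive semi-definite "
            f"(min eigenvalue {w.min():.3e})")
    return C


def sample_covariates(spec: CohortSpec) -> dict:
    """Draw the covariate table as a dict of name -> array(n_subjects)."""
    names = list(spec.marginals.keys())
    C = _copula_correlation(spec, names)
    rng = np.random.default_rng(spec.seed)
    w, V = np.linalg.eigh(C)
    A = V @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    z = rng.standard_normal((spec.n_subjects, len(names))) @ A.T
    u = stats.norm.cdf(z)
    out = {}
    for j, name in enumerate(names):
        dist, clip = spec.marginals[name]
        x = dist.ppf(np.clip(u[:, j], 1e-12, 1 - 1e-12))
        if clip is not None:
            x = np.clip(x, *clip)
        out[name] = x
    return out


def sample_cohort(spec: CohortSpec):
    """Sample ``n_subjects`` (PhantomSpec, ClinicalRecord) pairs.

    Deterministic for a given seed.  Geometry parameters are written into
    copies of the template phantom; body mass follows from BMI and height
    scaled to the template's foot size (mass itself is never re-sampled, so
    BMI drives the load model exactly as intended).
    """
    cov = sample_covariates(spec)
    # geometry varies multiplicatively around the template, so cohorts can
    # be generated at any template scale (including reduced test fixtures)
    depth_ref = float(spec.marginals["tissue_depth_mh1"][0].median())
    curv_ref = float(spec.marginals["mh1_curvature"][0].median())
    mass_ref = float(spec.marginals["bmi"][0].median()) * 1.62**2
    subjects = []
    for i in range(spec.n_subjects):
        mass = cov["bmi"][i] * cov["height"][i] ** 2
        ph = replace(
            spec.template,
            subject_id=f"S{i + 1:03d}",
            body_mass=float(spec.template.body_mass * mass / mass_ref),
            bmi=float(cov["bmi"][i]),
            tissue_depth_mh1=float(spec.template.tissue_depth_mh1
                                   * cov["tissue_depth_mh1"][i] / depth_ref),
            sesamoid_offset_frac=float(cov["sesamoid_offset_frac"][i]),
            mh1_medial_plantar_radius=float(
                spec.template.mh1_medial_plantar_radius
                * curv_ref / cov["mh1_curvature"][i]),
            seed=spec.seed + 1000 + i,
        )
        rec = ClinicalRecord(
            bmi=float(cov["bmi"][i]),
            disease_duration=float(cov["disease_duration"][i]),
            lfis_if=float(np.round(cov["lfis_if"][i])),
            instances_count=float(np.round(cov["instances_count"][i])),
        )
        subjects.append((ph, rec))
    return subjects
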