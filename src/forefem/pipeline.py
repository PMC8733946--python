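"""End-to-end orchestration: phantom -> morphometrics -> mesh -> solve -> metrics.

The pipeline turns one :class:`PhantomSpec` (or a sampled cohort) into the
four damage-risk metrics plus the morphological measures, with all
intermediate artifacts written to a run directory keyed by a configuration
hash.  Two protocol harnesses live here as well:

* :func:`convergence_study` - solves the same phantom at a ladder of mesh
  densities and reports the relative change of the percentile metrics
  against the finest level (the mesh-selection protocol);
* :func:`cut_edge_study` - extends the modelled section proximally and
  compares region-of-interest metrics against the baseline, verifying that
  the cut boundaries do not contaminate the metatarsal-head region.

The packaged :func:`fixture_spec` is a reduced-scale forefoot used by the
validation harnesses; its size and load were chosen so a full density
ladder solves on a single CPU in minutes (the methods note documents the
choices).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import labels as L
from . import metrics as MX
from . import morphometrics as MM
from .cohort import CohortSpec, sample_cohort
from .materials import MaterialLibrary
from .meshing import label_to_mesh
from .phantom import PhantomSpec, VoxelLabelMap, build_phantom, dress_phantom
from .solver import (BoundarySpec, SolverConfig, build_forefoot_model,
                     build_load_case, solve, equilibrium_check)

#: regions whose thin-feature resolvability is checked when meshing (the
#: fixed bones may be represented coarsely: they carry no strain field)
DEFORMABLE_LABELS = (L.SOFT_TISSUE, L.SKIN, L.SOCK, L.ORTHOSIS, L.SOLE,
                     L.UPPER)


@dataclass(frozen=True)
class DressSpec:
    """Worn-layer thicknesses (mm)."""

    sock: float = 2.0
    upper: float = 3.0
    sole: float = 6.0
    orthosis_min: float = 3.0


def fixture_spec():
    """The packaged reduced-scale fixture phantom and its dressing.

    A 0.3-scale forefoot with proportionally thicker worn layers (so one
    element spans each layer at the working density) and a load that puts
    peak tissue shear in the 10-20% range.
    """
    spec = PhantomSpec().scaled(0.30, voxel_size=1.5, skin_thickness=4.0,
                                tissue_depth_mh1=9.0, base_pad=4.0)
    spec = replace(spec, subject_id="fixture", body_mass=14.0,
                   section_length=12.0)
    dress = DressSpec(sock=4.0, upper=4.0, sole=6.0, orthosis_min=4.0)
    return spec, dress

#: lattice densities of the fixture convergence study (target edge, mm);
#: the study appends one nested 1:8 subdivision of the last level
FIXTURE_SIZING_LADDER = (5.0, 4.0)
#: the working lattice density used by the downstream analyses
FIXTURE_WORKING_SIZING = FIXTURE_SIZING_LADDER[1]
#: sensor-grid resolution used with the miniature fixture (the 5 mm
#: instrument convention scaled with the 0.3-scale anatomy)
FIXTURE_GRID_SPACING = 1.5


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    dress: DressSpec = field(default_factory=DressSpec)
    sizing: object = 4.0                      # scalar or region->mm mapping
    load_increments: int = 2
    solver: SolverConfig = field(default_factory=lambda: SolverConfig())
    grid_spacing: float = 5.0
    quadratic: bool = True
    measure_curvature: bool = True
    out_dir: Optional[str] = None
    write_artifacts: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("out_dir")
        blob = yaml.safe_dump(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["phantom"] = PhantomSpec(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in doc["phantom"].items()})
        doc["dress"] = DressSpec(**doc["dress"])
        doc["solver"] = SolverConfig(**doc["solver"])
        return cls(**doc)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and carries the cause."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _prepare_out(config: RunConfig, force: bool = False) -> Optional[Path]:
    if config.out_dir is None or not config.write_artifacts:
        return None
    out = Path(config.out_dir)
    h = config.config_hash()
    marker = out / "config_hash.txt"
    if out.exists() and marker.exists():
        old = marker.read_text().strip()
        if old != h and not force:
            raise FileExistsError(
                f"output dir {out} holds a run with different config hash "
                f"{old}; use force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    marker.write_text(h + "\n")
    config.to_yaml(out / "config.yaml")
    return out


def solve_phantom(spec: PhantomSpec, dress: DressSpec, sizing,
                  load_increments: int = 3,
                  solver: Optional[SolverConfig] = None,
                  quadratic: bool = True,
                  library: Optional[MaterialLibrary] = None):
    """Build, dress, mesh and solve one phantom; returns (result, mesh, map)."""
    anatomy = build_phantom(spec)
    dressed = dress_phantom(anatomy, sock_thickness=dress.sock,
                            upper_thickness=dress.upper,
                            sole_thickness=dress.sole,
                            orthosis_min=dress.orthosis_min)
    mesh = label_to_mesh(dressed, sizing, quadratic=quadratic,
                         thin_check=DEFORMABLE_LABELS)
    lib = library or MaterialLibrary.defaults()
    load = build_load_case(spec.body_mass, spec.section_length,
                           spec.full_foot_length, spec.mh_centers,
                           load_increments)
    model = build_forefoot_model(mesh, lib, BoundarySpec(), load)
    result = solve(model, solver or SolverConfig(),
                   load_increments=load_increments)
    return result, mesh, dressed, anatomy


def run_subject(config: RunConfig, force: bool = False):
    """One subject end to end; returns (MetricsRecord, MorphometricsRecord).

    Re-running with an identical config reproduces the metrics bit-for-bit
    (the whole chain is deterministic).
    """
    out = _prepare_out(config, force)
    t0 = time.time()
    try:
        anatomy = build_phantom(config.phantom)
    except Exception as e:
        raise StageError("phantom", e) from e
    try:
        morpho = MM.measure(anatomy, curvature=config.measure_curvature)
    except Exception as e:
        raise StageError("morphometrics", e) from e
    try:
        dressed = dress_phantom(anatomy, sock_thickness=config.dress.sock,
                                upper_thickness=config.dress.upper,
                                sole_thickness=config.dress.sole,
                                orthosis_min=config.dress.orthosis_min)
    except Exception as e:
        raise StageError("dress", e) from e
    try:
        mesh = label_to_mesh(dressed, config.sizing,
                             quadratic=config.quadratic,
                             thin_check=DEFORMABLE_LABELS)
    except Exception as e:
        raise StageError("mesh", e) from e
    try:
        load = build_load_case(config.phantom.body_mass,
                               config.phantom.section_length,
                               config.phantom.full_foot_length,
                               config.phantom.mh_centers,
                               config.load_increments)
        model = build_forefoot_model(mesh, MaterialLibrary.defaults(),
                                     BoundarySpec(), load)
        result = solve(model, config.solver,
                       load_increments=config.load_increments)
    except Exception as e:
        raise StageError("solve", e) from e
    try:
        rec = MX.compute_metrics(result, grid_spacing=config.grid_spacing,
                                 subject_id=config.phantom.subject_id,
                                 mesh_id=config.config_hash())
    except Exception as e:
        raise StageError("metrics", e) from e

    if out is not None:
        from . import io as fio
        dressed.save(str(out / "labels.nii.gz"))
        fio.write_mesh_vtu(out / "mesh.vtu", mesh)
        fio.write_result_vtu(out / "result.vtu", result)
        row = {**dataclasses.asdict(rec), **dataclasses.asdict(morpho),
               "runtime_s": round(time.time() - t0, 1),
               "seed": config.seed}
        pd.DataFrame([row]).to_csv(out / "metrics.csv", index=False)
        with open(out / "solve_log.json", "w") as fh:
            json.dump(result.log, fh, indent=1)
    return rec, morpho


def run_cohort(cohort: CohortSpec, config: RunConfig,
               out_dir: Optional[str] = None, reference: Optional[dict] = None):
    """Sample a cohort, run every subject, and screen the results.

    Individual subject failures are logged and excluded (with a count); if
    every subject fails the run errors out.  Returns
    ``(table, CohortSummary, correlation DataFrame, failures)``.
    """
    subjects = sample_cohort(cohort)
    rows = []
    failures = []
    for ph, rec in subjects:
        cfg = dataclasses.replace(config, phantom=ph, out_dir=None,
                                  write_artifacts=False)
        try:
            met, mor = run_subject(cfg)
        except (StageError, Exception) as e:   # noqa: BLE001 - log and go on
            failures.append({"subject": ph.subject_id, "error": str(e)})
            continue
        rows.append({
            "subject_id": ph.subject_id,
            "bmi": rec.bmi, "bmi_group": rec.bmi_group,
            "disease_duration": rec.disease_duration,
            "lfis_if": rec.lfis_if, "instances_count": rec.instances_count,
            "tissue_depth_mh1": mor.tissue_depth_mh1,
            "sesamoid_lateral_offset_pct": mor.sesamoid_lateral_offset_pct,
            "mh1_curvature": mor.mh1_curvature,
            "shear_p99": met.shear_p99,
            "vol_over_10pct": met.vol_over_10pct,
            "pressure_p99": met.pressure_p99,
            "max_pressure_gradient": met.max_pressure_gradient,
        })
    if not rows:
        raise RuntimeError(f"all {len(subjects)} subjects failed: {failures}")
    table = pd.DataFrame(rows)
    if len(table) >= 3:
        from . import stats as ST
        summary, corr = ST.summarize(table, reference)
    else:
        summary, corr = None, None      # correlations undefined below n=3
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort_metrics.csv", index=False)
        if summary is not None:
            summary.table.to_csv(out / "cohort_summary.csv", index=False)
            corr.to_csv(out / "cohort_correlations.csv", index=False)
        with open(out / "failures.json", "w") as fh:
            json.dump(failures, fh, indent=1)
    return table, summary, corr, failures


# ---------------------------------------------------------------------------
# protocol harnesses
# ---------------------------------------------------------------------------

def _embed_model_field(model_c, u_c, mesh_c, embed, model_f) -> np.ndarray:
    """Warm-start field for a subdivided model, kept body-pure.

    The solved field is discontinuous across the contact interface (foot
    and shoe sides own separate copies of the interface nodes), so the two
    bodies are embedded separately and reassembled on the fine model's
    node layout; mixing sides would inject penetration-scale errors into
    the stiff shoe layers and ruin the warm start.
    """
    n_c = mesh_c.n_nodes
    uc = np.asarray(u_c).reshape(-1, 3)
    glued = uc[:n_c].copy()                   # interface carries foot values
    shoe_field = glued.copy()
    shared_c = model_c.node_source[n_c:]
    shoe_field[shared_c] = uc[n_c:]
    shoe_parents = np.isin(mesh_c.region, L.SHOE_BODY)
    emb_foot = embed(glued, prefer_elems=~shoe_parents)
    emb_shoe = embed(shoe_field, prefer_elems=shoe_parents)
    foot_mask = np.zeros(len(model_f.nodes), dtype=bool)
    foot_mask[np.unique(model_f.tets[np.isin(model_f.region, L.FOOT_BODY)])] \
        = True
    src = model_f.node_source
    u0 = np.where(foot_mask[:, None], emb_foot[src], emb_shoe[src])
    return u0.ravel()


def convergence_study(spec: Optional[PhantomSpec] = None,
                      dress: Optional[DressSpec] = None,
                      sizings=FIXTURE_SIZING_LADDER,
                      subdivisions: int = 1,
                      load_increments: int = 1,
                      solver: Optional[SolverConfig] = None,
                      grid_spacing: float = FIXTURE_GRID_SPACING
                      ) -> pd.DataFrame:
    """Metric values across a mesh-density ladder, finest level last.

    The first levels are lattice densities; the working mesh (last lattice
    level) is then refined ``subdivisions`` times by nested 1:8 element
    subdivision, which halves the element size while keeping the
    discretized geometry bit-identical - the clean setting for judging FE
    convergence of the percentile metrics.  Each subdivided level is
    warm-started from the embedded coarser solution.  The returned frame
    carries per-level metrics plus ``rel_diff_*`` columns: the relative
    difference of each percentile metric against the finest level.
    """
    from . import solver as SV
    from .meshing import subdivide

    if spec is None or dress is None:
        fspec, fdress = fixture_spec()
        spec = spec or fspec
        dress = dress or fdress
    lib = MaterialLibrary.defaults()
    load = build_load_case(spec.body_mass, spec.section_length,
                           spec.full_foot_length, spec.mh_centers,
                           load_increments)
    rows = []
    cached = []
    mesh = result = None
    anatomy = build_phantom(spec)
    dressed = dress_phantom(anatomy, sock_thickness=dress.sock,
                            upper_thickness=dress.upper,
                            sole_thickness=dress.sole,
                            orthosis_min=dress.orthosis_min)

    def record(siz, mesh, result):
        rec = MX.compute_metrics(result, grid_spacing=grid_spacing)
        rows.append({"sizing_mm": siz, "n_elements": mesh.n_elements,
                     "n_nodes": mesh.n_nodes,
                     "shear_p99": rec.shear_p99,
                     "vol_over_10pct": rec.vol_over_10pct,
                     "pressure_p99": rec.pressure_p99,
                     "max_pressure_gradient": rec.max_pressure_gradient})
        cached.append(result)

    for siz in sizings:
        mesh = label_to_mesh(dressed, siz, thin_check=DEFORMABLE_LABELS)
        model = build_forefoot_model(mesh, lib, BoundarySpec(), load)
        result = solve(model, solver or SolverConfig(),
                       load_increments=load_increments)
        record(siz, mesh, result)

    siz = sizings[-1]
    model_c = result.model
    for _ in range(subdivisions):
        fine, embed = subdivide(mesh)
        model_f = build_forefoot_model(fine, lib, BoundarySpec(), load)
        u0 = _embed_model_field(model_c, result.u, mesh, embed, model_f)
        result = solve(model_f, solver or SolverConfig(),
                       load_increments=1, u0=u0)
        mesh, siz, model_c = fine, siz / 2.0, model_f
        record(siz, mesh, result)

    df = pd.DataFrame(rows)
    finest = df.iloc[-1]
    for m in ("shear_p99", "pressure_p99"):
        df[f"rel_diff_{m}"] = np.abs(df[m] - finest[m]) / finest[m]
    df.attrs["results"] = cached
    return df


def cut_edge_study(spec: Optional[PhantomSpec] = None,
                   dress: Optional[DressSpec] = None,
                   sizing=FIXTURE_WORKING_SIZING,
                   extend_frac: float = 0.25,
                   roi_margin_frac: float = 0.25,
                   load_increments: int = 1,
                   solver: Optional[SolverConfig] = None,
                   grid_spacing: float = FIXTURE_GRID_SPACING) -> dict:
    """Cut-edge proximity check: extend the section, compare ROI metrics.

    The phantom keeps its distal anatomy fixed (head positions are measured
    from the distal cut), so extending ``section_length`` by ``extend_frac``
    only adds proximal shaft.  Metrics are evaluated in a common distal
    region of interest that excludes ``roi_margin_frac`` of the original
    length next to the proximal cut; the relative change of each metric is
    returned.
    """
    if spec is None or dress is None:
        fspec, fdress = fixture_spec()
        spec = spec or fspec
        dress = dress or fdress
    L0 = spec.section_length
    h = spec.voxel_size
    # candidate extensions stay on the voxel lattice; among them prefer one
    # that also preserves the mesh lattice's axial cell size, so the region
    # of interest is discretized identically and the comparison isolates
    # the boundary-condition influence
    h0 = float(sizing) if np.isscalar(sizing) else min(
        float(v) for v in dict(sizing).values())

    def _axial_cell(section):
        nz = int(np.ceil(section / h - 1e-9)) + 1
        extent = nz * h
        nb = max(1, int(np.ceil(extent / h0 - 1e-9)))
        return extent / nb

    base_cell = _axial_cell(L0)
    cands = [np.round(extend_frac * L0 / h) * h + k * h for k in range(-2, 4)]
    cands = [c for c in cands if c > 0]
    dL = min(cands, key=lambda c: abs(_axial_cell(L0 + c) - base_cell))
    # the subject's foot is unchanged: only the modelled section grows, so
    # the load scale per unit section length is preserved
    spec_ext = replace(spec, section_length=L0 + dL)

    res0, _, _, _ = solve_phantom(spec, dress, sizing, load_increments, solver)
    res1, _, _, _ = solve_phantom(spec_ext, dress, sizing, load_increments,
                                  solver)
    win0 = (roi_margin_frac * L0, L0)
    win1 = (dL + roi_margin_frac * L0, dL + L0)
    rec0 = MX.compute_metrics(res0, z_window=win0, grid_spacing=grid_spacing)
    rec1 = MX.compute_metrics(res1, z_window=win1, grid_spacing=grid_spacing)
    out = {"baseline": rec0, "extended": rec1, "rel_change": {}}
    for m in ("shear_p99", "vol_over_10pct", "pressure_p99",
              "max_pressure_gradient"):
        a, b = getattr(rec0, m), getattr(rec1, m)
        denom = max(abs(a), 1e-12)
        out["rel_change"][m] = abs(b - a) / denom
    return out
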