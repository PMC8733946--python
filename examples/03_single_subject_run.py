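"""One subject end to end: phantom -> mesh -> midstance solve -> metrics.

Uses the packaged reduced-scale fixture (a miniature forefoot whose worn
layers are proportionally thickened so coarse meshes resolve them); the
full-scale default phantom runs the same way, just longer.  Prints the four
damage-risk metrics: higher shear percentiles / volumes indicate more
internal tissue distortion around the bones; the pressure numbers describe
the orthosis interface loading at in-shoe-sensor resolution.
"""

import time

from forefem import pipeline as PL

spec, dress = PL.fixture_spec()
# curvature needs finer voxels than the miniature carries; the full-scale
# default phantom measures it (see example 01)
cfg = PL.RunConfig(phantom=spec, dress=dress,
                   sizing=PL.FIXTURE_WORKING_SIZING,
                   load_increments=1, write_artifacts=False,
                   measure_curvature=False,
                   grid_spacing=PL.FIXTURE_GRID_SPACING)

t0 = time.time()
metrics, morpho = PL.run_subject(cfg)
print(f"solved in {time.time() - t0:.0f} s")
print(f"subject mass {spec.body_mass} kg, section {spec.section_length} mm")
print(f"tissue depth under MH1: {morpho.tissue_depth_mh1:.1f} mm, "
      f"sesamoid offset {morpho.sesamoid_lateral_offset_pct:.1f}%")
print(f"99th% shear strain:         {metrics.shear_p99:8.2f} %")
print(f"volume over 10% shear:      {metrics.vol_over_10pct:8.1f} mm^3")
print(f"99th% plantar pressure:     {metrics.pressure_p99:8.1f} kPa")
print(f"max pressure gradient:     {metrics.max_pressure_gradient:8.2f} kPa/mm")
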