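"""Build one synthetic phantom and extract its geometric predictors.

A grade-III phantom has a spherical tumor touching the brainstem slab.
The printed feature vector is the 9-predictor input of the Random
Forest: the tumor volume (mm^3), seven shortest distances (mm) to the
adjacent structures, and the contact area (mm^2) with the ipsilateral
cerebellum.  Touching structures measure one voxel spacing (0.8 mm),
never zero, because distances are between voxel centers.
"""

from koosgrade import Side, extract_features, make_phantom, to_ipsi_contra
from koosgrade.phantom import Ellipsoid, PhantomSpec

spec = PhantomSpec(
    tumor=Ellipsoid(center=(45.2, 30.0, 32.0), radii=(8.0, 8.0, 8.0)),
    side=Side.RIGHT,
    grade=3,
)
case = make_phantom(spec, case_id="demo")

print(f"planted grade: {case.grade}, planted side: {case.side.value}")
print(f"analytic tumor volume: {case.truth['tumor_volume_mm3']:.1f} mm^3")
print(f"analytic brainstem surface gap: {case.truth['brainstem_gap_mm']:.3f} mm\n")

canonical = to_ipsi_contra(case.volumes["ceT1"], case.side)
fv = extract_features(canonical, case.case_id)
print(fv.to_series().round(2).to_string())
print(
    "\nThe extracted volume tracks the analytic sphere volume to ~1%, and "
    "the brainstem distance of 0.8 mm (one voxel) encodes 'touching'."
)
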