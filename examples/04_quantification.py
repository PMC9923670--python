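"""Scalar PET/MRI/IFL quantification on synthetic ground-truth inputs."""

from metaconn import (
    PhantomSpec,
    corrected_lesion_volume,
    decay_correct,
    generate_ifl_image,
    generate_phantom,
    immunopositive_density,
    percent_id_per_gram,
    voi_means,
)
from metaconn.regions import Region, RegionSet

# --- VOI means from a digital phantom (exact, no partial volume)
regions = RegionSet([
    Region("left_voi", "left VOI", "L", "subcortical", 1),
    Region("right_voi", "right VOI", "R", "subcortical", 2),
])
intensity, labels = generate_phantom(PhantomSpec(activities={1: 5.0, 2: 10.0}))
print(voi_means(intensity, labels, regions).to_string(index=False))

# --- decay correction and %ID/g
activity = decay_correct(5.0, dt_min=109.8)  # one F-18 half-life
print(f"activity back-corrected over one half-life: {activity:.1f} kBq/cc")
uptake = percent_id_per_gram(activity, injected_dose_MBq=10.0)
print(f"uptake: {uptake:.2f} %ID/g")

# --- hemisphere-ratio lesion volume correction
m = corrected_lesion_volume(raw_mm3=100.0, ipsi_mm3=550.0, contra_mm3=495.0)
print(f"corrected lesion volume: {m.corrected_volume_mm3:.1f} mm^3 "
      "(raw deflated because the lesioned hemisphere is swollen)")

# --- immunopositive pixel density with automatic (Otsu) threshold
image, true_fraction = generate_ifl_image((512, 512), 0.25, contrast=1.0, seed=3)
density, threshold = immunopositive_density(image, "otsu")
print(f"immunopositive density: {density:.4f} (truth {true_fraction}), "
      f"threshold {threshold:.3f}")
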