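"""Generate a small synthetic onset/apex thermogram cohort.

Each subject gets two 8-bit grayscale frames: onset (emotion start, the
thermal baseline) and apex (peak intensity, with class-dependent regional
temperature changes, small head motion and sensor noise). The manifest
records the ground-truth motion and occlusion flags.
"""

from pathlib import Path

from thermaffect import EMOTIONS, generate_cohort
from thermaffect.synthetic import CohortConfig

out = Path("scratch/example_cohort")
config = CohortConfig(n_per_class={e: 3 for e in EMOTIONS})
records, manifest = generate_cohort(config, seed=0, out_dir=out)

print(f"wrote {len(records)} pairs ({2 * len(records)} PNGs) to {out}/")
print(manifest[["subject_id", "emotion", "motion_rotation", "motion_dx"]].head(6))

rec = records[0]
truth = rec.truth
print(f"\nsubject {rec.subject_id}: true per-region apex deltas (degC)")
for region, delta in truth.region_delta.items():
    print(f"  {region:12s} {delta:+.3f}")
# The deltas are the generator's ground truth; the pipeline must recover
# them from the images alone.
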