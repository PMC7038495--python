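"""Per-day abundance time series from classified detections.

Plants known daily rockfish counts, rebuilds the per-day series from
labelled detection records, and compares an automatic series against a
manual one the way an observatory analyst would.
"""

from benthoscan.evaluation import compare_series, detection_time_series
from benthoscan.synth import SceneSpec, generate_sequence

spec = SceneSpec(days=5, frames_per_day=1,
                 planting={"rockfish": [2, 0, 3, 1, 4]}, seed=13)
frames, records = generate_sequence(spec)
day_of = {f.image_id: f.day for f in frames}
detections = [(r.image_id, day_of[r.image_id], r.class_label) for r in records]

auto = detection_time_series(detections, "rockfish",
                             date_range=(frames[0].day, frames[-1].day))
print("automatic series:", [(str(d), c) for d, c in auto.points])
print(f"total detections: {auto.total} in {auto.images_with_detection} images")

# a manual count that missed one animal on the last day
manual = detection_time_series(detections[:-1], "rockfish",
                               date_range=(frames[0].day, frames[-1].day),
                               source="manual")
comparison = compare_series(auto, manual)
print("\nper-day difference (auto - manual):", comparison["difference"].tolist())
print(f"totals: auto {comparison.attrs['auto_total']} vs "
      f"manual {comparison.attrs['manual_total']}; images with detections: "
      f"{comparison.attrs['auto_images_with_detection']} vs "
      f"{comparison.attrs['manual_images_with_detection']}")
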