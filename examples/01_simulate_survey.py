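"""Simulate a double-observer aerial bear survey and write it to disk.

Generates a Katmai-Preserve-scale survey (288 transects, 15 km target
length, 800 m one-sided truncation distance) with a humped two-piece normal
detection curve peaking 300 m off the line, and writes transects.csv,
detections.csv and truth.json into ./survey_run/.
"""
from bearsurv import TruthConfig, expected_detections, simulate_survey, simulate_to_dir

truth = TruthConfig(seed=42)
dataset, record = simulate_survey(truth)

print(f"study area          {truth.study_area_km2:,.0f} km^2")
print(f"transects           {len(dataset.transects)} x {truth.transect_length_km} km, "
      f"w = {truth.w_m:.0f} m")
print(f"true abundance      {record['N_bears']:.0f} bears "
      f"({record['N_groups']:.0f} groups)")
print(f"expected detections {expected_detections(truth):.0f}")
print(f"realized detections {dataset.n_detections}")
# each detection row: perpendicular distance, group size, capture history
d = dataset.detections[0]
print(f"first detection     {d.distance_m:.0f} m, group of {d.group_size}, "
      f"history {d.history.value}")

out = simulate_to_dir(truth, "survey_run")
print(f"wrote {out}/transects.csv, detections.csv, truth.json")
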