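#!/usr/bin/env python
"""Generate the demo cohort: ocean field, three tagged fish, receiver
stations, acoustic detections and recapture events.

Writes the full dataset (NetCDF field, GeoJSON areas, CSV series,
detections, stations, recaptures, truth) under results/demo/data/.
"""

from _demo import RESULTS, announce, demo_config

from basstrack.pipeline import stage_simulate


def main() -> None:
    announce("simulate")
    cfg = demo_config()
    data = stage_simulate(cfg, RESULTS)
    field = data["field"]
    print(f"grid: {len(field.lats)}x{len(field.lons)} cells, "
          f"{int(field.water_mask.sum())} water")
    for truth in data["truths"]:
        print(f"{truth.tag_id}: {truth.n_days} days, "
              f"{int(truth.states.sum())} high-activity days")
    print(f"detections: {data['detections'].n_detections}, "
          f"recaptures: {len(data['recaptures'])}")
    print(f"written to {RESULTS/'data'}")


if __name__ == "__main__":
    main()
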