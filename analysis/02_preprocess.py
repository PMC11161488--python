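#!/usr/bin/env python
"""Clean the demo cohort: depth-drift correction, daily summaries,
mortality and inshore truncation, plume flagging, detection QC.

Writes per-tag daily summaries and the QC report under
results/demo/clean/.
"""

from _demo import RESULTS, announce, demo_config

from basstrack.pipeline import stage_preprocess, stage_simulate


def main() -> None:
    announce("preprocess")
    cfg = demo_config()
    data = stage_simulate(cfg, RESULTS)
    pre = stage_preprocess(cfg, data, RESULTS)
    print(f"detection QC removed: {pre['qc_counts']}")
    for tag_id, cs in pre["cleans"].items():
        flagged = sum(o.cooling_water for o in cs.daily)
        print(f"{tag_id}: {len(cs.daily)} daily records, "
              f"alive until {cs.alive_until}, {flagged} cooling-water days")
    print(f"written to {RESULTS/'clean'}")


if __name__ == "__main__":
    main()
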