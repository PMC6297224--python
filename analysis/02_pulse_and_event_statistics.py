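#!/usr/bin/env python
"""Pulse and low-growth-event statistics of the simulated ensembles.

For both feedback conditions: detects RpoS-concentration pulses (5-frame
smoothing, 7-frame unsmoothed window heights), low-growth events below the
survival-predictive threshold (0.71/h), the complementary duration
distribution, and the lag-0 growth/[RpoS] cross-correlation.  Writes pulse
heights, event durations and the duration CCDFs to results/ and prints the
headline comparison.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from rpospulse import SimParams, knockout_params
from rpospulse.pipelines import DEFAULT_LOW_GROWTH_THRESHOLD, ensemble_stats


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("-n", type=int, default=300)
    ap.add_argument("--threshold", type=float,
                    default=DEFAULT_LOW_GROWTH_THRESHOLD)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    p = SimParams()
    stats = {}
    for label, pp in (("wt", p), ("knockout", knockout_params(p))):
        s = ensemble_stats(pp, args.n, args.seed, threshold=args.threshold)
        stats[label] = s
        pd.DataFrame({"height": s.pulse_heights}).to_csv(
            args.out_dir / f"pulse_heights_{label}.tsv", sep="\t",
            index=False)
        pd.DataFrame({"duration_h": s.event_durations_h}).to_csv(
            args.out_dir / f"event_durations_{label}.tsv", sep="\t",
            index=False)
        s.duration_ccdf().to_csv(
            args.out_dir / f"event_duration_ccdf_{label}.tsv", sep="\t",
            index=False)
        print(f"{label}: {s.n_pulses} pulses ({s.pulses_per_hour:.3f}/h), "
              f"{s.n_events} events ({s.events_per_hour:.3f}/h), "
              f"lag-0 corr {s.lag0_corr_mean:+.3f} "
              f"+/- {s.lag0_corr_std:.3f}")
    wt, ko = stats["wt"], stats["knockout"]
    for d in (1.0, 2.0, 4.0):
        pw = float(np.mean(wt.event_durations_h >= d))
        pk = float(np.mean(ko.event_durations_h >= d))
        print(f"P(event duration >= {d:.0f} h): wt {pw:.4f}  knockout {pk:.4f}")
    print("finding: the feedback makes slow-growth episodes both more "
          "frequent and far longer-lived, while slightly reducing the "
          "number of distinct RpoS pulses (episodes merge).")


if __name__ == "__main__":
    main()
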