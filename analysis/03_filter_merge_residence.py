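#!/usr/bin/env python
"""Merge per-frame localizations into binding events; recover residence times.

Reads the bright-site acquisition from 01, links localizations across
frames (20 nm radius, max 1 off-frame), writes the merged table and the
residence-time histogram, and reports the exponential mean recovered from
the chain-length statistics.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from paintkit import io as iokit
from paintkit import linking

BASE = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main():
    BASE.mkdir(parents=True, exist_ok=True)
    table = iokit.read_localization_csv(SCRATCH / "data" / "bright.csv")
    merged = linking.merge_localizations(table, radius=20.0, max_off_frames=1)
    linking.merged_to_table(merged, table).to_csv(
        SCRATCH / "merged_bright.csv", index=False, float_format="%.4f")

    counts, edges = linking.residence_histogram(merged, bin_width=0.05)
    pd.DataFrame({"residence_s": edges[:-1], "count": counts}).to_csv(
        BASE / "residence_histogram.tsv", sep="\t", index=False)

    tau = linking.mean_residence_mle(merged, table.exposure)
    print(f"{len(table)} localizations -> {len(merged)} binding-event chains")
    print(f"recovered mean residence time: {tau*1000:.1f} ms "
          f"(simulated: 100 ms exponential)")
    print(f"chain-length distribution: "
          f"{np.bincount([m.n_frames for m in merged])[1:6].tolist()} "
          f"chains of 1..5 frames")


if __name__ == "__main__":
    main()
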