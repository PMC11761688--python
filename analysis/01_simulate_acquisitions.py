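#!/usr/bin/env python
"""Simulate the synthetic acquisitions used throughout the analysis.

Generates three direct-mode localization tables with known ground truth and
writes them (plus scene/trace tables) under results/data/:

* nuclear.csv    — 1000 clustered binding-site "clutches" (sd 50 nm) over a
                   200 um field, 100 s at 50 ms exposure, 20 nm precision.
* bright.csv     — 500 isolated bright sites at 5 nm precision, 100 s; used
                   for residence-time recovery.
* roi.csv        — dense 10 um ROI (~1e5 localizations over 200 s) for FRC.
"""

from pathlib import Path

from paintkit import io as iokit
from paintkit import localize, sim

OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"
SEED = 1010


def simulate(name, scene, kin, precision, seed):
    trace = sim.simulate_binding(scene, kin, seed)
    table = sim.events_to_localizations(scene, trace, kin, precision, seed + 1)
    filtered = localize.filter_precision(table, 30.0)
    iokit.write_scene_tsv(scene, OUT / f"{name}_scene.tsv")
    iokit.write_trace_tsv(trace, OUT / f"{name}_trace.tsv")
    iokit.write_localization_csv(filtered, OUT / f"{name}.csv")
    print(f"{name}: {scene.n_sites} sites, {trace.n_events} binding events, "
          f"{len(filtered)} localizations ({len(filtered)/kin.duration:.0f}/s)")


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    simulate("nuclear",
             sim.make_clutch_scene(1000, 6, 50.0, (200_000.0, 200_000.0), SEED),
             sim.KineticsParams(site_on_rate=0.02, mean_residence=0.1,
                                duration=100.0, exposure=0.05),
             precision=20.0, seed=SEED + 1)

    simulate("bright",
             sim.make_clutch_scene(500, 1, 50.0, (100_000.0, 100_000.0), SEED + 10),
             sim.KineticsParams(site_on_rate=0.05, mean_residence=0.1,
                                duration=100.0, exposure=0.05),
             precision=5.0, seed=SEED + 11)

    simulate("roi",
             sim.make_clutch_scene(300, 20, 50.0, (10_000.0, 10_000.0), SEED + 20),
             sim.KineticsParams(site_on_rate=0.05, mean_residence=0.1,
                                duration=200.0, exposure=0.05),
             precision=20.0, seed=SEED + 21)


if __name__ == "__main__":
    main()
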