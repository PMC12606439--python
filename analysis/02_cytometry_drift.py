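#!/usr/bin/env python
"""Process simulated timer-reporter cytometry and quantify drift removal.

Simulates one BY and one RM sample with a configured activity difference and
an injected linear acquisition-time drift, applies size gating and loess
time correction, and reports how well the configured difference is recovered
with and without the correction.  Writes results/cytometry_summaries.tsv.
"""

from pathlib import Path

import numpy as np

from bsa_gxe.cytometry import summaries_to_frame, summarize_replicate
from bsa_gxe.simulate import simulate_cytometry_events
from bsa_gxe.studies import run_drift_correction_study

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
DELTA = 0.6  # configured BY-RM activity difference


def main() -> None:
    OUT.mkdir(exist_ok=True)
    summaries = []
    for strain, activity in (("BY", 1.0), ("RM", 1.0 + DELTA)):
        for rep in range(4):
            ev = simulate_cytometry_events(
                activity=activity, gfp_level=1000, n_events=10_000,
                drift_slope=0.03, noise_sd=0.25, seed=SEED * 100 + rep * 2
                + (strain == "RM"))
            summaries.append(summarize_replicate(
                ev, strain=strain, reporter="Asn", environment="SC",
                replicate=f"r{rep}"))
    frame = summaries_to_frame(summaries)
    frame.to_csv(OUT / "cytometry_summaries.tsv", sep="\t", index=False)
    by = frame[frame.strain == "BY"]["activity"].mean()
    rm = frame[frame.strain == "RM"]["activity"].mean()
    print(f"configured activity difference: {DELTA}")
    print(f"recovered (time-corrected medians): {rm - by:.3f}")
    drift = run_drift_correction_study(SEED)
    print(f"injected slope {drift['injected_slope']}, residual slope "
          f"{drift['residual_slope']:.2e} "
          f"(ratio {drift['slope_ratio']:.1e}); mean shift "
          f"{drift['mean_shift']:.1e}")
    print(f"wrote {OUT / 'cytometry_summaries.tsv'}")


if __name__ == "__main__":
    main()
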