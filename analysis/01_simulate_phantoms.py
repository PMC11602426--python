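#!/usr/bin/env python
"""Generate the synthetic study datasets with known ground truth.

Writes image phantoms (control and GPN-like regimes) as OME-TIFF under
scratch/, and their ground-truth tables plus calcium-trace and per-fish
count tables as CSV under results/sim/.
"""

from pathlib import Path

import pandas as pd

from haircelltox.calcium import traces_to_frame
from haircelltox.io import write_stack
from haircelltox.synthetic_data import (
    CountPhantomParams,
    StackPhantomParams,
    TracePhantomParams,
    gen_calcium_traces,
    gen_doseresponse_counts,
    gen_neuromast_stack,
    gpn_like,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "sim"  # regenerable inputs, not analysis outputs
SCRATCH = ROOT / "scratch" / "sim"

# calcium regimes: responder fractions and mitoGCaMP peak statistics of the
# three exposure conditions (acute 100 uM neomycin, delayed 100 uM G418,
# acute 400 uM G418); the delayed/acute-G418 peak parameters interpolate
# between the published acute and delayed summaries
TRACE_REGIMES = {
    "neo100_acute": dict(n_dying=16, responder_fraction=1.0, peak_mean=2.2, peak_sd=0.46),
    "g418_100_delayed": dict(n_dying=11, responder_fraction=2 / 11, peak_mean=1.2, peak_sd=0.32),
    "g418_400_acute": dict(n_dying=14, responder_fraction=10 / 14, peak_mean=1.7, peak_sd=0.40),
}

# dose-response designs: (drug, paradigm, HC50 uM, dose grid)
NEO_DOSES = (0.0, 12.5, 25.0, 50.0, 100.0, 200.0, 400.0)
GENT_DOSES = (0.0, 5.0, 10.0, 20.0, 40.0, 80.0, 200.0, 400.0)
COUNT_DESIGNS = [
    ("neomycin", "acute_1h", 44.0, NEO_DOSES),
    ("neomycin", "chronic_24h", 25.0, NEO_DOSES),
    ("neomycin", "washout_1p23h", 94.0, NEO_DOSES),
    ("gentamicin", "chronic_24h", 10.0, GENT_DOSES),
    ("gentamicin", "washout_1p23h", 19.0, GENT_DOSES),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    print("== image phantoms (5 control + 5 GPN-like neuromasts) ==")
    for regime, make in [
        ("control", lambda s: StackPhantomParams(seed=s, snr=30.0, diffuse_fraction=0.05)),
        ("gpn", lambda s: gpn_like(StackPhantomParams(seed=s, snr=30.0, diffuse_fraction=0.05))),
    ]:
        base_seed = 100 if regime == "control" else 200
        for i in range(5):
            stack, truth = gen_neuromast_stack(make(base_seed + i))
            write_stack(stack, SCRATCH / f"{regime}_{i}.ome.tif")
            truth.vesicle_table.to_csv(OUT / f"{regime}_{i}_vesicle_truth.csv", index=False)
            truth.seeds.to_csv(OUT / f"{regime}_{i}_seeds.csv")
            print(f"  {regime} #{i}: {len(truth.vesicle_table)} vesicles, "
                  f"{truth.cells.n_labels} cells")

    print("== calcium trace sets ==")
    frames = []
    for condition, kw in TRACE_REGIMES.items():
        traces, truth = gen_calcium_traces(
            TracePhantomParams(seed=300, n_living=4, condition=condition, **kw)
        )
        frames.append(traces_to_frame(traces))
        truth.to_csv(OUT / f"traces_{condition}_truth.csv", index=False)
        print(f"  {condition}: {kw['n_dying']} dying cells, "
              f"{int(truth.responder_true.sum())} true responders")
    pd.concat(frames).to_csv(OUT / "calcium_traces.csv", index=False, float_format="%.4f")

    print("== per-fish count tables ==")
    tables = []
    for i, (drug, paradigm, hc50, doses) in enumerate(COUNT_DESIGNS):
        params = CountPhantomParams(
            true_hc50_um=hc50, doses_um=doses, seed=400 + i, drug=drug, paradigm=paradigm
        )
        tables.append(gen_doseresponse_counts(params).assign(true_hc50_um=hc50))
        print(f"  {drug} {paradigm}: HC50 {hc50} uM, {len(tables[-1])} fish")
    pd.concat(tables).to_csv(OUT / "doseresponse_counts.csv", index=False)
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
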