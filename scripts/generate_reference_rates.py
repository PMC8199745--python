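#!/usr/bin/env python
"""Regenerate the shipped reduced-sampling reference rate table.

A cached rate table for small knots lets network examples and tests run
without hours of Monte Carlo.  The sampling size is deliberately small; the
stored standard errors reflect that.
"""

import os
import sys
import time

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from knotflux import fixtures_io as fio  # noqa: E402
from knotflux import polymer_mc as pm  # noqa: E402
from knotflux import topoii_model as tm  # noqa: E402

SAMPLING = {"0.1": 300, "3.1-": 400, "4.1": 150, "5.1-": 700, "5.2-": 200}
SEED = 2024


def main(out=None):
    if out is None:
        out = os.path.join(os.path.dirname(__file__), "..", "src",
                           "knotflux", "data", "reference_rates.json")
    os.makedirs(os.path.dirname(out), exist_ok=True)
    par = pm.ChainParameters()
    ests = []
    for i, (label, n) in enumerate(SAMPLING.items()):
        t0 = time.time()
        est = tm.estimate_rates(par, label, n_samples=n,
                                rng_seed=SEED + 100 * i)
        print(f"{label}: j={est.j:.2e} ({est.n_juxtaposed} events, "
              f"{time.time() - t0:.0f}s)", flush=True)
        ests.append(est)
    fio.write_rates_json(out, ests, meta={
        "seed": SEED, "sampling": SAMPLING,
        "note": "reduced-sampling reference rates for tests/examples"})
    print(f"wrote {out}")


if __name__ == "__main__":
    main(sys.argv[1] if len(sys.argv) > 1 else None)
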