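#!/usr/bin/env python
"""Regenerate the shipped knot fingerprint table.

The table is built programmatically (4-plat realizations validated against
tabulated Alexander polynomials); this script dumps it to CSV so the
fingerprints can be inspected and diffed.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from knotflux import knot_invariants as ki  # noqa: E402


def main(out=None):
    if out is None:
        out = os.path.join(os.path.dirname(__file__), "..", "src",
                           "knotflux", "data", "knot_table.csv")
    os.makedirs(os.path.dirname(out), exist_ok=True)
    rows = ["label,det1,det2,alexander,homfly"]
    for e in ki.knot_table():
        alex = " ".join(str(c) for c in e.alexander)
        hom = ";".join(f"{i}:{j}:{c}" for i, j, c in e.homfly_key)
        rows.append(f"{e.knot},{e.det1},{e.det2},{alex},{hom}")
    with open(out, "w") as fh:
        fh.write("\n".join(rows) + "\n")
    print(f"wrote {len(rows) - 1} fingerprints to {out}")


if __name__ == "__main__":
    main(sys.argv[1] if len(sys.argv) > 1 else None)
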