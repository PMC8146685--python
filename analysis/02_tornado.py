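#!/usr/bin/env python
"""One-way deterministic sensitivity analysis (tornado diagram data).

Re-runs the full two-strategy comparison at each parameter's low and
high sensitivity bound and writes results/tornado.csv, sorted widest bar
first. The monthly SSA drug cost is expected to dominate; no single
parameter range should pull the ICER below the $100,000/QALY threshold.
"""

import subprocess
import sys


def main() -> None:
    subprocess.run([sys.executable, "-m", "gepnet_cea.cli", "tornado",
                    "--out", "results"], check=True)
    print("Wrote results/tornado.csv (one bar per Table-1 parameter range).")


if __name__ == "__main__":
    main()
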