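#!/usr/bin/env python
"""Threshold price of the SSA: the monthly drug cost at which immediate
initiation becomes cost-effective.

Root-finds the monthly octreotide cost on [0, base price] such that the
recomputed ICER equals the $100,000/QALY willingness-to-pay threshold,
and writes results/threshold.json. The answer is roughly two orders of
magnitude below the US list price.
"""

import subprocess
import sys


def main() -> None:
    subprocess.run([sys.executable, "-m", "gepnet_cea.cli", "threshold",
                    "--out", "results"], check=True)
    print("Wrote results/threshold.json.")


if __name__ == "__main__":
    main()
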