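"""One-command analysis bundle plus a sociogram export.

Equivalent to `groupnet analyze` on CSV inputs: runs every stage for a
synthetic East-like colony and writes matrices, networks, metric
tables, permutation tests and a run log to an output directory.
"""

from pathlib import Path

import groupnet as gn
from groupnet.plotting import plot_sociogram

outdir = Path("scratch_example_bundle")
config = gn.AnalysisConfig(
    synthetic=gn.east_like(seed=11),
    iterations=200, burn_in=500, swaps_per_iteration=5,
    seed=99, outdir=outdir,
)
results = gn.run_analysis(config)
print(gn.format_report(results))

group = next(iter(results["groups"]))
net = gn.read_network(outdir / group / "network.graphml")
plot_sociogram(net, outdir / group / "sociogram.png", seed=0)
print(f"\nbundle written to {outdir}/ (sociogram: {group}/sociogram.png)")
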