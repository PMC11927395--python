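"""Generate a fully synthetic test dataset: reference, reads, signals, truth.

Artifact (FP) loci get deletion basecalls whose current signal matches the
non-deleted template; genuine (TP) loci get reads whose signal truly lacks
the deleted base and shifts by 3 sigma in the flanks.
"""

import pandas as pd

from delsieve import FixtureSpec
from delsieve.simulate import write_fixture_bundle

spec = FixtureSpec(n_variants=8, depth_per_stratum=40, muaf=0.5, seed=42)
paths = write_fixture_bundle(spec, "example_out/fixture")

print("files written:")
for name, path in paths.items():
    print(f"  {name:10s} {path}")

truth = pd.read_csv(paths["truth"], sep="\t")
print("\ntruth table (one row per planned deletion locus):")
print(truth.to_string(index=False))
print(
    "\n'truth' FP = basecall artifact to be removed, TP = genuine deletion;"
    "\n'observed_muaf' is the realized deletion-read fraction per locus."
)
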