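"""Find pathways whose enrichment changes along the trajectory.

Builds a ten-cluster enrichment table with three planted time trends among
flat decoys, fits the spline trend model per pathway, and prints the
multiple-testing-adjusted results: the planted pathways should surface at
the top with small adjusted p-values.
"""

import numpy as np
import pandas as pd

from tempotraj import detect_trends, trend_table
from tempotraj.enrichment import EnrichmentMatrix

rng = np.random.default_rng(0)
clusters = [f"K{j}" for j in range(10)]
T = np.linspace(1, 4, 10)  # temporal scores of the ten clusters

rows = {
    "rising_linear": 0.6 * T + rng.normal(scale=0.2, size=10),
    "falling_linear": -0.5 * T + rng.normal(scale=0.2, size=10),
    "transient_peak": np.exp(-((T - 2.5) ** 2)) + rng.normal(scale=0.1, size=10),
}
for d in range(20):
    rows[f"flat_{d:02d}"] = rng.normal(scale=0.2, size=10)

E = EnrichmentMatrix(pd.DataFrame(rows).T.set_axis(clusters, axis=1))
results = detect_trends(E, dict(zip(clusters, T)), alpha=0.05)

table = trend_table(results)
print(table.head(8).to_string(index=False))
n_sig = int(table["significant"].sum())
print(f"\n{n_sig} of {len(table)} pathways significant at adjusted p < 0.05; "
      "the three planted trends should rank first, flat decoys last.")
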