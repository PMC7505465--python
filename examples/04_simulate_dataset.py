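"""Write a synthetic planted-lineage data set in the standard input formats.

The generator emits everything the pipeline consumes -- a dense expression
TSV, a per-cell label table, pathway gene sets in GMT, and the true lineage
as a gold-standard edge list -- so the whole tool can be exercised from
files alone (see the `tempotraj` command line interface).
"""

from pathlib import Path

import tempotraj as tt
from tempotraj import write_expression, write_gmt, write_labels

out = Path("scratch/example_dataset")
out.mkdir(parents=True, exist_ok=True)

sim = tt.simulate(tt.SimulationSpec(seed=42, cells_per_cluster=40))
write_expression(sim.expression, out / "expression.tsv")
write_labels(sim.labels, out / "labels.tsv")
write_gmt(sim.pathways, out / "pathways.gmt")
sim.truth.write_tsv(out / "gold.tsv")

print(f"wrote {sim.expression.n_genes} genes x {sim.expression.n_cells} cells to {out}/")
print(f"  pathway sets: {len(sim.pathways)} (incl. 20 decoys of background genes)")
print(f"  true lineage: {', '.join(f'{u}->{v}' for u, v, _ in sim.truth.edges)}")
print("\nreproduce the trajectory from these files with:")
print(f"  tempotraj run --expression {out}/expression.tsv --labels {out}/labels.tsv \\")
print(f"      --gmt {out}/pathways.gmt --out scratch/example_run --n-pcs 5")
print(f"  tempotraj evaluate --pred scratch/example_run/trajectory.tsv "
      f"--gold {out}/gold.tsv")
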