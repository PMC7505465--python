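"""Score an inferred trajectory against a curated gold standard.

Shows the two scores used for benchmarking: the undirected mismatch
(graph-edit) count and the directed-edge F1, plus marker-root orientation
for methods that output undirected trajectories.
"""

from tempotraj import LabeledGraph, f1_score, mismatch_score, orient_from_root

gold = LabeledGraph(
    nodes=["myoblast", "intermediate", "myotube", "fibroblast"],
    edges=[
        ("myoblast", "intermediate", "forward"),
        ("intermediate", "myotube", "forward"),
        ("myoblast", "fibroblast", "forward"),
    ],
)

# a prediction that skips the intermediate state on the myotube branch
pred = LabeledGraph(
    nodes=["myoblast", "intermediate", "myotube", "fibroblast"],
    edges=[
        ("myoblast", "intermediate", "forward"),
        ("myoblast", "myotube", "forward"),
        ("myoblast", "fibroblast", "forward"),
    ],
)

res = f1_score(pred, gold)
print(f"mismatch score: {res.mismatch} (node + undirected adjacency differences)")
print(f"precision {res.precision:.2f}, recall {res.recall:.2f}, F1 {res.f1:.2f}")
print(f"  true positive edges: {res.tp}")
print(f"  false positives: {res.fp}")
print(f"  false negatives: {res.fn}")

# an undirected prediction (e.g. from an MST method) oriented from a
# marker-identified root before scoring
undirected = LabeledGraph(
    nodes=gold.nodes,
    edges=[(u, v, "undirected") for u, v, _ in gold.edges],
)
oriented = orient_from_root(undirected, {"myoblast"})
res2 = f1_score(oriented, gold)
print(f"\nundirected prediction oriented outward from 'myoblast': "
      f"F1 {res2.f1:.2f}, mismatch {mismatch_score(oriented, gold)}")
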