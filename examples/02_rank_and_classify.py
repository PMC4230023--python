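"""Score interaction reliability, filter noise proteins, rank the rest.

Uses a small hand-built network: a 4-clique (a putative complex) attached
through a connector protein to a loose path.  Shows the per-edge
reliability scores, the noise classification and the importance ranking
that together pick the complex seeds.
"""

from prorankplus import (
    PPINetwork,
    PruningParams,
    adjustcd_scores,
    classify_proteins,
    ordered_essentials,
    rank_proteins,
)

edges = [
    ("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D"),
    ("D", "X"), ("X", "Y"), ("Y", "Z"),
]
net = PPINetwork.from_edges(edges)

scores = adjustcd_scores(net, PruningParams(iterations=2))
print("edge reliability (shared-neighborhood score, 2 rounds):")
for (u, v), s in sorted(scores.items()):
    print(f"  {u}-{v}: {s:.3f}")
# clique edges score high (many shared partners); the D-X connector has no
# shared neighbors and falls below the unweighted pruning cutoff 0.45.

cls = classify_proteins(net)
print("labels:", dict(sorted(cls.labels.items())))
# A, B, C stay essential; D, X, Y have disconnected or near-isolated
# neighborhoods (bridge), and the path end Z is a shore protein.

rank = rank_proteins(net)
print("seed order:", ordered_essentials(rank, cls))
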