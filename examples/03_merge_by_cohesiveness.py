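"""Merge two overlapping complexes and expand the union greedily.

Two triangles sharing one protein are merged; the union is then grown by
admitting neighbors whenever the cohesiveness w_in/(w_in + w_out + p) does
not decrease.  With p=0 and no edges leaving the union, cohesiveness
reaches its boundary-free maximum of 1.
"""

from prorankplus import (
    Complex,
    PPINetwork,
    ProteinClassification,
    cohesiveness,
    merge_by_cohesiveness,
)

net = PPINetwork.from_edges(
    [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("c", "e"), ("d", "e")]
)
cls = ProteinClassification({u: "essential" for u in net.nodes})
c1 = Complex(frozenset("abc"), essential_members=frozenset("abc"))
c2 = Complex(frozenset("cde"), essential_members=frozenset("cde"))

print("cohesiveness of {a,b,c} alone (p=0):", cohesiveness(net, c1.members, 0.0))
merged = merge_by_cohesiveness(net, c1, c2, cls, penalty=0.0)
print("merged members:", sorted(merged.members))
print("cohesiveness of the merged complex:", cohesiveness(net, merged.members, 0.0))
# 3/(3+2) = 0.6 for the lone triangle (two edges leave it through c);
# the 5-protein union has no outgoing edges, so cohesiveness is 1.0.
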