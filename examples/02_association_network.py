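"""From point samples to an SRI network and its node metrics.

Uses a tiny hand-written observation log to show every intermediate
object: point samples -> group-by-individual matrix -> dyadic SRI ->
weighted network -> per-node metric table.
"""

import groupnet as gn

roster = [
    gn.IndividualRecord("Ana", "capuchin", "F", "demo"),
    gn.IndividualRecord("Rio", "capuchin", "M", "demo"),
    gn.IndividualRecord("Pip", "squirrel_monkey", "F", "demo"),
    gn.IndividualRecord("Sol", "squirrel_monkey", "F", "demo"),
]
samples = [
    gn.PointSample("p1", "Ana", frozenset({"Rio"})),
    gn.PointSample("p2", "Ana", frozenset({"Rio", "Pip"})),
    gn.PointSample("p3", "Rio", frozenset()),            # solitary focal
    gn.PointSample("p4", "Pip", frozenset({"Sol"})),
    gn.PointSample("p5", "Sol", frozenset({"Pip"})),
    gn.PointSample("p6", "Pip", frozenset({"Sol"})),
]

gbi = gn.build_gbi(samples, roster)
print("group-by-individual matrix (rows = sampling periods):")
print(gbi.to_dataframe().to_string())

matrix = gn.association_matrix(gbi)
print("\nSRI association matrix:")
print(matrix.to_dataframe().round(3).to_string())
print("e.g. Ana-Rio: together in 2 of the 3 periods either was seen -> 2/3.")

net = gn.build_network(matrix, roster=roster)
print(f"\nnetwork density: {gn.density(net):.3f}")
print("\nper-node metrics (weighted geodesics = sums of SRI weights):")
print(gn.node_metrics(net).round(3).to_string())
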