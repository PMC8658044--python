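# Hand-transcribed worked-example pair: a four-node chain G1 and the graph
# G2 obtained from it by the six-operation transformation
#   delete node [1], delete single edge, insert node [5], insert single edge,
#   substitute node [7] by [2], substitute single edge by double edge.
# G2's exact topology is a synthetic reconstruction consistent with that
# operation list (only the operations, not G2's layout, are authoritative).

graph G1
n n1 [1]
n n2 [6]
n n3 [5]
n n4 [7]
e n1 n2 -
e n2 n3 -
e n3 n4 -

graph G2
n a [6]
n b [5]
n c [2]
n d [5]
e a b =
e b c -
e b d -
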