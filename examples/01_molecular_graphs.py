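"""Build the directed molecular graph and similarity objects for a molecule.

The directed graph is what the message-passing network consumes: every
bond becomes two opposite directed edges paired by ``reverse_edge``.
"""

from lipotask import build_directed_graph, fingerprint, murcko_scaffold, tanimoto

g = build_directed_graph("Cc1ccccc1O")  # o-cresol
print(f"atoms: {g.n_atoms}, directed edges: {g.n_directed_edges}")
print(f"reverse-edge pairing of edge 0: {g.reverse_edge[0]} (and back: "
      f"{g.reverse_edge[g.reverse_edge[0]]})")

fp_a = fingerprint("Cc1ccccc1O")
fp_b = fingerprint("Cc1ccccc1N")  # o-toluidine
print(f"fingerprint bits set: {int(fp_a.sum())}")
print(f"Tanimoto(o-cresol, o-toluidine) = {tanimoto(fp_a, fp_b):.3f}")
print(f"Murcko scaffold of o-cresol: {murcko_scaffold('Cc1ccccc1O')!r}")
# The scaffold strips both substituents: only the benzene ring remains,
# so both molecules land in the same scaffold-split partition.
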