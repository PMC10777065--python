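"""Generate a synthetic circRNA-miRNA interaction dataset.

Builds a bipartite network with planted block structure (community-linked
molecules interact preferentially) and sequences carrying block-specific
motif pairs, then writes FASTA files, the positive edge list, and a JSON
truth sidecar.
"""

from spbcmi import synthetic_data as sd

fixture = sd.gen_fixture(sd.FixtureSpec(seed=42))
paths = sd.write_fixture(fixture, "scratch/example_fixture")

print(f"circRNAs: {len(fixture.circ_records)}")
print(f"miRNAs:   {len(fixture.mir_records)}")
print(f"positive interactions: {len(fixture.positive_pairs)}")
print(f"files: {sorted(p.name for p in paths.values())}")
# Each block of the planted partition owns one (circRNA motif, miRNA motif)
# pair; interacting molecules carry their block's motif, so both the graph
# and the sequences are informative about interaction.
motifs = fixture.truth["motifs"]
for block, (cm, mm) in motifs.items():
    print(f"block {block}: circ motif {cm}, mir motif {mm}")
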