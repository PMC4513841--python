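"""Screen toxin genes for use as counterselection markers in a target strain.

A synthetic hit table stands in for blastn output: each gene x genome pair
gets alignment fragments realising a controlled query coverage.  Genes are
called present at >= 80% merged coverage; candidates are genes absent from
the target strain, ranked by absence across a reference panel.
"""
from negselect import PanelSpec, candidate_toxins, presence_matrix, simulate_hit_table

panel = PanelSpec(
    genomes=["UTI89", "CFT073", "EDL933", "Sakai"],
    genes=[("relE", 288), ("mqsR", 297), ("ydaS", 230)],
    presence={
        ("relE", "CFT073"): 0.95,          # present in one panel genome only
        ("mqsR", "UTI89"): 1.00,           # present in the target -> excluded
        ("mqsR", "CFT073"): 0.90,
        ("ydaS", "EDL933"): 0.79,          # below the 80% cutoff -> absent
    },
    fragmentation=2,
)

hits = simulate_hit_table(panel, seed=7)
matrix = presence_matrix(hits, panel.gene_lengths, threshold=0.80, genomes=list(panel.genomes))
print("coverage matrix:")
print(matrix.coverage.round(3))

candidates = candidate_toxins(matrix, target_genome="UTI89", panel=["CFT073", "EDL933", "Sakai"])
print("\ncandidates (absent from UTI89, ranked by panel absence):")
print(candidates.to_string(index=False))
# 'majority_absent' flags genes missing from strictly more than half of the
# panel: safe bets for a cassette that should not meet a resident antitoxin.
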