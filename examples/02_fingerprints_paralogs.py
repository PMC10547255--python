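"""Extract zinc fingerprints from proteins and cluster paralogs.

Finds C2H2 fingers with the regex surrogate for the Pfam zf-C2H2 model,
reads the -1/+3/+6 recognition-helix residues of each finger, and groups
proteins whose fingerprints share >= 60% residue identity (best ungapped
sliding alignment) into single-linkage paralog sets.
"""

from kzfptools.fingerprint import (
    cluster_paralogs, fingerprint_from_protein, fingerprint_identity,
)
from kzfptools import synthetic as syn

# Zif268 finger 1: the classic worked example — fingerprint reads R, E, R
zif = fingerprint_from_protein("PYACPVESCDRRFSRSDELTRHIRIHTGQK", "Zif268_F1")
print("Zif268 finger-1 triplet:", zif.triplets)  # ['RER']

# synthetic proteins with planted triplets round-trip exactly
genome = syn.generate_genome(1, {"chr1": 10_000_000}, [])
_, prots, truth = syn.generate_kzfp_genes(genome, 6, [], (3, 6), seed=5)
fps = [fingerprint_from_protein(p, g) for g, p in prots.items()]
for fp in fps[:2]:
    print(fp.protein_id, "planted", truth.fingerprints[fp.protein_id],
          "recovered", fp.triplets)

print("identity(fp0, fp1) =", round(fingerprint_identity(fps[0], fps[1]), 3))
print("paralog sets at 60%:", cluster_paralogs(fps, threshold=0.60))
# Random fingerprints rarely reach 60% identity, so most sets are singletons;
# duplicated genes (near-identical fingerprints) would merge into one set.
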