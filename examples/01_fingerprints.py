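"""Encode molecules into topological pharmacophore fingerprints.

Builds the feature graph of aspirin and prints its three fingerprint
variants.  The set bits mark which (feature-family pair, distance bin)
combinations occur in the molecule; e.g. an acceptor and a donor 3-7 bonds
apart light the long-distance bin of the acceptor-donor pair key.
"""

import phoregen as pg
from phoregen.features import FAMILIES

aspirin = "CC(=O)Oc1ccccc1C(=O)O"
mol = pg.parse_molecule(aspirin)
feats = pg.detect_features(mol)
graph = pg.build_graph(mol, feats)

print(f"aspirin: {len(feats)} pharmacophore features")
for f in feats:
    print(f"  {FAMILIES[f.family]:18s} atoms {sorted(f.member_atoms)}")

for variant in ("P72", "P108", "P1032"):
    fp = pg.fingerprint(aspirin, variant)
    print(f"{variant}: length {len(fp)}, {int(fp.bits.sum())} bits set")
# The 1032-bit variant starts with the 72-bit two-point fingerprint and
# appends 960 three-point bits (120 family triples x 8 bin patterns).
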