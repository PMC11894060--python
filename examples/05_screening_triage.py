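"""Run the post-generation screening triage on a toy scored table.

Records carry externally produced docking scores and polar-interaction
flags.  The pipeline keeps molecules pharmacophorically similar to the
reference, drug-like, novel, well-docked with the requisite hinge contact,
then clusters scaffolds and ranks representatives by docking score and
ligand efficiency (docking score / molecular weight).
"""

import pandas as pd

import phoregen as pg
from phoregen.design import TriageConfig, triage

reference = "CCCCc1ccc(CC(=O)N)cc1"  # toy reference ligand

records = pd.DataFrame(
    {
        "smiles": [
            "CCCCc1ccc(CC(=O)N)cc1",        # near-identical to reference
            "CCCCc1ccc(CCC(=O)N)cc1",       # close analogue
            "CCOc1ccc(CC(=O)N)cc1",         # analogue, weaker docking
            "CCCCc1ccc(CC(=O)O)cc1",        # acid analogue, no Cys133 contact
            "c1ccccc1",                     # dissimilar
        ],
        "docking_score": [-10.2, -9.8, -8.1, -9.5, -7.0],
        "interactions": [
            "Cys133;Lys82",
            "Cys133;Glu140;Asp194",
            "Cys133;Lys82",
            "Lys82;Asp194",
            "",
        ],
    }
)

result = triage(records, reference, TriageConfig(pharma_min=0.85, keep_n=10))
print("stage counts:", result.stage_counts)
print(result.survivors[["smiles", "docking_score", "ligand_efficiency", "rank"]])
# Survivors passed every gate; the acid analogue fell at the docking stage
# because the requisite Cys133 contact is missing.
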