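"""Synthetic SMILES corpora with controllable pharmacophore content.

Corpus molecules are assembled from small pre-validated building blocks
(hydroxyls, amines, amides, acids, nitriles, phenyl rings, thioethers)
joined by alkyl linkers of varying length, so that pairwise feature
distances sweep both the short ([0,3)) and long ([3,8)) bins of the
two-bin discretization.  Assembly is plain valence-safe concatenation of
fragments written to chain left-to-right; no general molecule mutation is
attempted.  Every emitted SMILES is checked to parse and to tokenize under
the pruned 94-token vocabulary, and generation is a pure function of the
corpus spec (n_molecules, seed, linker range).

These corpora stand in for large public training sets at desk scale: they
exercise the fingerprint, model and metric machinery end to end, but make
no attempt to emulate the property distribution of real screening
libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from . import features as F
from .vocab import Vocabulary, canonical_vocab

__all__ = [
    "ToyCorpusSpec",
    "make_corpus",
    "worked_molecules",
    "charged_molecules",
]

# building blocks; attachment points are the string ends, so concatenating
# start + linker + (mid + linker) + end is always a valid SMILES chain
_START = ["O", "N", "C", "c1ccccc1", "OC(=O)", "CC(=O)N", "CS", "N#C"]
_MID = ["", "O", "N", "C(=O)N", "c1ccccc1"]
_END = ["O", "N", "C", "c1ccccc1", "C(=O)O", "C(=O)N", "SC", "C#N"]


@dataclass(frozen=True)
class ToyCorpusSpec:
    """Deterministic recipe for a toy corpus."""

    n_molecules: int = 200
    seed: int = 7
    min_linker: int = 1
    max_linker: int = 6

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if not 1 <= self.min_linker <= self.max_linker:
            raise ValueError("need 1 <= min_linker <= max_linker")


def _assemble(start: str, k1: int, mid: str, k2: int, end: str) -> str:
    if mid:
        return start + "C" * k1 + mid + "C" * k2 + end
    return start + "C" * k1 + end


def make_corpus(spec: ToyCorpusSpec, vocabulary: Vocabulary | None = None
                ) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Build (smiles, P72 fingerprint, feature-count vector) triples.

    The block/linker grid is enumerated, deduplicated by canonical SMILES,
    shuffled with the spec seed and truncated to ``n_molecules``.  Raises
    if the grid cannot supply enough distinct molecules.
    """
    vocab = vocabulary or canonical_vocab(pruned=True)
    linkers = range(spec.min_linker, spec.max_linker + 1)
    candidates = []
    seen = set()
    for start in _START:
        for end in _END:
            for mid in _MID:
                for k1 in linkers:
                    for k2 in linkers if mid else [0]:
                        smi = _assemble(start, k1, mid, k2, end)
                        mol = Chem.MolFromSmiles(smi)
                        if mol is None:
                            continue
                        can = Chem.MolToSmiles(mol)
                        if can in seen:
                            continue
                        vocab.tokenize(smi)  # raises on OOV; contract check
                        seen.add(can)
                        candidates.append(smi)
    if spec.n_molecules > len(candidates):
        raise ValueError(
            f"grid holds only {len(candidates)} distinct molecules, "
            f"{spec.n_molecules} requested"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(candidates))[: spec.n_molecules]
    out = []
    for i in order:
        smi = candidates[int(i)]
        fp = F.fingerprint(smi, "P72").bits
        counts = F.feature_counts(smi)
        out.append((smi, fp, counts))
    return out


def worked_molecules() -> dict[str, str]:
    """The fixed named molecules used across examples and tests."""
    return {
        "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
        "ethanol": "CCO",
        "methane": "C",
        "ethane": "CC",
        "benzene": "c1ccccc1",
        "toluene": "Cc1ccccc1",
        "diol": "OCCCO",
        "charged_amine": "CC[NH3+]",
        "no_cut_ring": "c1ccccc1",
    }


def charged_molecules() -> list[str]:
    """Ten charged species for exercising charge neutralization."""
    return [
        "[NH3+]CC",
        "CC(=O)[O-]",
        "c1ccccc1C(=O)[O-]",
        "CC[NH2+]CC",
        "C[NH+](C)C",
        "[O-]S(=O)(=O)c1ccccc1",
        "[NH3+]CCC(=O)[O-]",
        "c1cc[nH+]cc1",
        "CC(=O)OCC[N+](C)(C)C",
        "[O-]c1ccccc1",
    ]
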