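"""Evaluation metrics for pharmacophore-conditioned generation.

Structural similarity (S_struct) is the Tanimoto coefficient of 2048-bit
radius-2 Morgan fingerprints; pharmacophoric similarity (S_pharma) is the
Tanimoto coefficient of ErG reduced-graph fingerprints.  Molecules are
charge-neutralized before scoring.  The feature-count deviation D_count is
the mean, over generated molecules, of the L1 distance between their
8-long pharmacophore feature-count vectors and the reference's.  Recall
and apparent precision quantify rediscovery of reserved active ligands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.rdReducedGraphs import GetErGFingerprint
from rdkit import DataStructs

from .features import feature_counts, parse_molecule

__all__ = [
    "RecallResult",
    "neutralize",
    "s_struct",
    "s_pharma",
    "d_count",
    "recall_rate",
    "apparent_precision",
]

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

# Atom-by-atom neutralization: protonated centers with removable H+ and
# deprotonated centers that can accept H+ are returned to neutral form.
# Quaternary ammonium (charged, no H) is untouchable and left as is.
_NEUTRALIZE = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


def neutralize(smiles: str) -> str:
    """Return the charge-neutralized canonical SMILES.  Idempotent."""
    mol = parse_molecule(smiles)
    at_matches = mol.GetSubstructMatches(_NEUTRALIZE)
    if at_matches:
        mol = Chem.RWMol(mol)
        for (idx,) in at_matches:
            atom = mol.GetAtomWithIdx(idx)
            chg = atom.GetFormalCharge()
            h = atom.GetTotalNumHs()
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(max(0, h - chg))
            atom.UpdatePropertyCache()
        mol = mol.GetMol()
        Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _mol_neutral(smiles: str):
    return parse_molecule(neutralize(smiles))


def s_struct(a: str, b: str) -> float:
    """Morgan (radius 2, 2048 bits) Tanimoto after neutralization."""
    fa = _MORGAN.GetFingerprint(_mol_neutral(a))
    fb = _MORGAN.GetFingerprint(_mol_neutral(b))
    return DataStructs.TanimotoSimilarity(fa, fb)


def s_pharma(a: str, b: str) -> float:
    """ErG-fingerprint Tanimoto after neutralization.

    ErG vectors are non-negative reals; the continuous Tanimoto
    a.b / (|a|^2 + |b|^2 - a.b) is used, which reduces to the binary
    Tanimoto on 0/1 vectors and is 1 exactly for identical vectors.
    """
    va = GetErGFingerprint(_mol_neutral(a))
    vb = GetErGFingerprint(_mol_neutral(b))
    num = float(np.dot(va, vb))
    den = float(np.dot(va, va) + np.dot(vb, vb) - num)
    if den == 0.0:
        return 1.0 if np.array_equal(va, vb) else 0.0
    return num / den


def d_count(generated: list[str], reference: str) -> float:
    """Mean L1 deviation of per-family feature counts from the reference."""
    if not generated:
        raise ValueError("empty generated list")
    ref = feature_counts(reference)
    total = 0.0
    for smi in generated:
        total += float(np.abs(feature_counts(smi) - ref).sum())
    return total / len(generated)


@dataclass
class RecallResult:
    recall: float
    n_recalled: int
    n_reserved: int
    relaxed_threshold: float | None = None


def _canonical_set(smiles_list) -> dict[str, str]:
    out = {}
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is not None:
            out.setdefault(Chem.MolToSmiles(parse_molecule(neutralize(smi))), smi)
    return out


def recall_rate(generated_set, reserved_actives, relaxed_threshold: float | None = None
                ) -> RecallResult:
    """Fraction of reserved actives found in the generated set.

    Exact mode matches neutralized canonical SMILES.  Relaxed mode also
    counts a reserved active as recalled when any generated molecule has
    s_struct >= relaxed_threshold to it.
    """
    if not reserved_actives:
        raise ValueError("empty reserved set")
    gen = _canonical_set(generated_set)
    res = _canonical_set(reserved_actives)
    recalled = {c for c in res if c in gen}
    if relaxed_threshold is not None:
        gen_fps = [_MORGAN.GetFingerprint(parse_molecule(c)) for c in gen]
        for c in res:
            if c in recalled or not gen_fps:
                continue
            fp = _MORGAN.GetFingerprint(parse_molecule(c))
            sims = DataStructs.BulkTanimotoSimilarity(fp, gen_fps)
            if max(sims) >= relaxed_threshold:
                recalled.add(c)
    return RecallResult(
        recall=len(recalled) / len(res),
        n_recalled=len(recalled),
        n_reserved=len(res),
        relaxed_threshold=relaxed_threshold,
    )


def apparent_precision(generation_stream, reserved_actives, budget: int = 4000,
                       threshold: float | None = 0.8) -> int:
    """Known actives found in the high-confidence generated set.

    The high-confidence set collects molecules sampled more than once in
    the raw stream, in order of their first repeat, until *budget* entries
    are gathered.  A reserved active counts if it appears in that set
    exactly (neutralized canonical SMILES) or, when *threshold* is given,
    if some set member reaches that structural similarity to it.
    """
    if budget <= 0:
        raise ValueError("budget must be positive")
    seen: set[str] = set()
    high_conf: list[str] = []
    in_high: set[str] = set()
    for smi in generation_stream:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen and can not in in_high:
            in_high.add(can)
            high_conf.append(can)
            if len(high_conf) >= budget:
                break
        seen.add(can)
    if not high_conf:
        return 0
    result = recall_rate(high_conf, reserved_actives, relaxed_threshold=threshold)
    return result.n_recalled
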