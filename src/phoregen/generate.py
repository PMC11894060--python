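"""Sampling molecules from a trained decoder under pharmacophore conditions.

De novo generation draws tokens one at a time from softmax(logits / t)
starting after the condition prefix and the begin token; scaffold
elaboration additionally forces the token sequence of a core fragment as a
prefix, so every sample extends the core.  The fragmentation protocol cuts
one random acyclic single bond between two heavy atoms of a conditioning
compound, yielding a core fragment (the generation prefix) and a reference
fragment (whose fingerprint becomes the condition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from . import model as M
from .features import parse_molecule

__all__ = [
    "GenerationRequest",
    "FragmentPair",
    "NoCutError",
    "sample",
    "fragment_molecule",
    "elaborate",
    "postprocess",
]


@dataclass
class GenerationRequest:
    """What to sample: how many, how hot, how long, from which seed."""

    n_samples: int = 100
    temperature: float = 0.7  # low-temperature default of the screening protocol
    max_length: int = 128
    seed: int = 0
    greedy: bool = False

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class FragmentPair:
    core: str
    reference: str
    broken_bond: tuple[int, int]


class NoCutError(ValueError):
    """Molecule has no acyclic single bond between two heavy atoms."""


def _sample_tokens(state: M.DecoderState, cond, prefix_ids, request: GenerationRequest,
                   vocabulary) -> list[list[int]]:
    """Batched autoregressive decoding; returns token-id lists without
    the begin token or the terminating pad."""
    cfg = state.config
    rng = np.random.default_rng(request.seed)
    B = request.n_samples
    pad = vocabulary.pad_id
    seqs = np.tile(np.asarray(prefix_ids, dtype=np.int64), (B, 1))
    cond_batch = None
    if cfg.cond_len:
        cond_batch = np.tile(np.asarray(cond, dtype=np.int64), (B, 1))
    alive = np.ones(B, dtype=bool)
    max_new = min(request.max_length, cfg.max_seq_len - cfg.cond_len - seqs.shape[1])
    for _ in range(max_new):
        if not alive.any():
            break
        probs = M.next_token_probs(state.params, cfg, cond_batch, seqs,
                                   temperature=request.temperature)
        if request.greedy:
            nxt = probs.argmax(-1)
        else:
            u = rng.random((B, 1))
            nxt = (probs.cumsum(-1) > u).argmax(-1)
        nxt = np.where(alive, nxt, pad)
        seqs = np.concatenate([seqs, nxt[:, None]], axis=1)
        alive &= nxt != pad
    out = []
    for row in seqs:
        toks = [int(t) for t in row[1:]]  # drop begin token
        if pad in toks:
            toks = toks[: toks.index(pad)]
        out.append(toks)
    return out


def sample(state: M.DecoderState, request: GenerationRequest, vocabulary,
           condition=None) -> list[str]:
    """Draw ``n_samples`` raw SMILES strings (validity not guaranteed).

    ``condition`` must match the model's condition kind: a fingerprint bit
    vector, an 8-long count vector, or None for an unconditional model.
    Deterministic given the request seed.
    """
    cfg = state.config
    if cfg.cond_len and condition is None:
        raise ValueError(f"model expects a {cfg.condition_kind} condition")
    prefix = [vocabulary.begin_id]
    token_rows = _sample_tokens(state, condition, prefix, request, vocabulary)
    return [vocabulary.decode([vocabulary.begin_id] + row) for row in token_rows]


# ---------------------------------------------------------------------------
# fragmentation


def _eligible_bonds(mol) -> list:
    """Acyclic single bonds between two heavy atoms (never to hydrogens)."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        out.append(bond)
    return out


def _fragment_smiles(mol, attach_idx: int, frag_atoms: set[int], want_attach_last: bool) -> str:
    """SMILES of one fragment.  For the core we need the attachment atom
    written last so that appending tokens extends the molecule from the cut
    point; we search the roots for one whose output order ends there."""
    em = Chem.RWMol(mol)
    for idx in sorted((a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in frag_atoms),
                      reverse=True):
        em.RemoveAtom(idx)
    frag = em.GetMol()
    Chem.SanitizeMol(frag)
    old_sorted = sorted(frag_atoms)
    new_attach = old_sorted.index(attach_idx)
    if not want_attach_last:
        return Chem.MolToSmiles(frag, rootedAtAtom=new_attach)
    for root in range(frag.GetNumAtoms()):
        smi = Chem.MolToSmiles(frag, rootedAtAtom=root)
        if _output_order(frag)[-1] == new_attach:
            return smi
    # Canonical branch ordering never leaves the attachment atom last (it
    # happens for e.g. amide attachments where =O outranks the N).  Renumber
    # the atoms along a DFS that defers the attachment-containing branch and
    # emit a non-canonical SMILES following that order.
    order = _dfs_deferring(frag, new_attach)
    renum = Chem.RenumberAtoms(frag, order)
    smi = Chem.MolToSmiles(renum, canonical=False, rootedAtAtom=0)
    if _output_order(renum)[-1] == order.index(new_attach):
        return smi
    # The attachment atom is a branching center no traversal can end at
    # (e.g. an amide carbonyl carbon).  Root at it and wrap the trailing
    # chain as a parenthesized branch, so the string still ends with the
    # root's open valence: C(N)=O becomes C(N)(=O).
    return _wrap_trailing(Chem.MolToSmiles(frag, rootedAtAtom=new_attach))


def _output_order(mol) -> list[int]:
    return list(map(int, mol.GetProp("_smilesAtomOutputOrder")[1:-1].rstrip(",").split(",")))


def _wrap_trailing(rooted_smiles: str) -> str:
    """Turn 'R(branch)...tail' into 'R(branch)...(tail)' where R is the
    first (root) atom, so that concatenating more SMILES extends R."""
    s = rooted_smiles
    i = 0
    # root atom token
    if s[i] == "[":
        i = s.index("]", i) + 1
    elif s[i : i + 2] in ("Cl", "Br"):
        i += 2
    else:
        i += 1
    # ring-closure digits on the root (optionally preceded by a bond symbol)
    while i < len(s):
        if s[i].isdigit():
            i += 1
        elif s[i] == "%" and i + 2 < len(s):
            i += 3
        elif s[i] in "-=#:" and i + 1 < len(s) and (s[i + 1].isdigit() or s[i + 1] == "%"):
            i += 1
        else:
            break
    # existing branches of the root
    while i < len(s) and s[i] == "(":
        depth = 0
        for j in range(i, len(s)):
            depth += s[j] == "("
            depth -= s[j] == ")"
            if depth == 0:
                i = j + 1
                break
    tail = s[i:]
    if not tail:
        return s
    return s[:i] + "(" + tail + ")"


def _dfs_deferring(mol, attach: int) -> list[int]:
    """A DFS atom order that always explores the branch leading toward
    ``attach`` last, so the attachment atom is written last."""
    n = mol.GetNumAtoms()
    # distance from every atom to the attachment, to know which neighbor
    # leads toward it
    dist = Chem.GetDistanceMatrix(mol)[:, attach]
    start_candidates = sorted(range(n), key=lambda a: -dist[a])
    order: list[int] = []
    seen = set()
    stack = [start_candidates[0]]
    while stack:
        a = stack.pop()
        if a in seen:
            continue
        seen.add(a)
        order.append(a)
        nbrs = [b.GetIdx() for b in mol.GetAtomWithIdx(a).GetNeighbors()
                if b.GetIdx() not in seen]
        # push the attachment-ward neighbors first so they are popped last
        nbrs.sort(key=lambda b: (dist[b], b))
        stack.extend(nbrs)
    return order


def fragment_molecule(smiles: str, seed: int = 0) -> FragmentPair:
    """Cut one random eligible bond; the core keeps its attachment atom as
    the final SMILES atom (extendable prefix), the reference fragment is
    rooted at its attachment atom."""
    mol = parse_molecule(smiles)
    bonds = _eligible_bonds(mol)
    if not bonds:
        raise NoCutError(f"no acyclic single heavy-atom bond to cut in {smiles!r}")
    rng = np.random.default_rng(seed)
    bond = bonds[int(rng.integers(len(bonds)))]
    i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    if rng.random() < 0.5:
        i, j = j, i  # randomize which side becomes the core
    em = Chem.RWMol(mol)
    em.RemoveBond(i, j)
    broken = em.GetMol()
    frags = Chem.GetMolFrags(broken)
    side_i = next(set(f) for f in frags if i in f)
    side_j = next(set(f) for f in frags if j in f)
    core = _fragment_smiles(mol, i, side_i, want_attach_last=True)
    reference = _fragment_smiles(mol, j, side_j, want_attach_last=False)
    return FragmentPair(core=core, reference=reference, broken_bond=(i, j))


def elaborate(state: M.DecoderState, core_smiles: str, condition,
              request: GenerationRequest, vocabulary) -> list[str]:
    """Scaffold elaboration: sample with the core's tokens forced as a
    prefix.  Every returned string begins with the core prefix verbatim."""
    core_tokens = vocabulary.tokenize(core_smiles)
    prefix = [vocabulary.begin_id] + [vocabulary.index[t] for t in core_tokens]
    if len(prefix) >= request.max_length + 1:
        raise ValueError("core fragment longer than max_length")
    token_rows = _sample_tokens(state, condition, prefix, request, vocabulary)
    return [vocabulary.decode([vocabulary.begin_id] + row) for row in token_rows]


# ---------------------------------------------------------------------------
# postprocessing


def postprocess(raw: list[str]) -> list[str]:
    """Drop unparseable strings, canonicalize, dedupe by canonical SMILES,
    preserving first-occurrence order."""
    seen = set()
    out = []
    for smi in raw:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can not in seen:
            seen.add(can)
            out.append(can)
    return out
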