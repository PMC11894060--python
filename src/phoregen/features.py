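"""Topological pharmacophore features and binary fingerprints.

A molecule is reduced to a graph of pharmacophore features (H-bond
acceptors/donors, aromatic rings, ionizable groups, hydrophobes, lumped
hydrophobes and Zn binders) with the shortest bond-count path between every
feature pair.  Pairs (and triples) of features are encoded into fixed-length
binary fingerprints by discretizing the pairwise distances into short/long
(2-bin) or short/medium/long (3-bin) ranges; distances of 8 bonds or more
fall outside every bin and contribute nothing ("null signals").

Fingerprint variants:

* ``P72``   — two-point pairs, 2-bin scheme: 36 family pairs x 2 bins.
* ``P108``  — two-point pairs, 3-bin scheme: 36 family pairs x 3 bins.
* ``P1032`` — the 72-bit two-point segment concatenated with a 960-bit
  three-point segment (120 family triples x 8 short/long bin patterns).

Feature SMARTS definitions are pinned in ``data/feature_definitions.smarts``
so detected features do not drift with toolkit upgrades.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem

__all__ = [
    "FAMILIES",
    "MAX_DISTANCE",
    "TWO_BIN",
    "THREE_BIN",
    "BinScheme",
    "PharmacophoreFeature",
    "PharmacophoreGraph",
    "Fingerprint",
    "InvalidSmilesError",
    "load_feature_definitions",
    "parse_molecule",
    "detect_features",
    "build_graph",
    "encode_two_point",
    "encode_three_point",
    "fingerprint",
    "feature_counts",
    "pair_layout",
    "triple_layout",
]

#: Fixed total order of the eight feature families; defines the bit layout.
FAMILIES = (
    "acceptor",
    "donor",
    "aromatic",
    "pos_ionizable",
    "neg_ionizable",
    "hydrophobe",
    "lumped_hydrophobe",
    "zn_binder",
)
N_FAMILIES = len(FAMILIES)

#: Distances >= MAX_DISTANCE bonds fall outside every bin (null signal).
MAX_DISTANCE = 8


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed and sanitized."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass(frozen=True)
class BinScheme:
    """Discretization of topological distances into half-open integer bins.

    ``ranges`` are (lo, hi) with lo inclusive, hi exclusive, except that
    ``lo_exclusive[i]`` marks a bin whose lower bound is itself excluded
    (the 3-bin short range is printed as the open interval (0, 2)).
    """

    name: str
    ranges: tuple[tuple[int, int], ...]
    lo_exclusive: tuple[bool, ...]

    @property
    def n_bins(self) -> int:
        return len(self.ranges)

    def bin_index(self, distance: int) -> int | None:
        """Bin containing *distance*, or None outside every bin."""
        for i, (lo, hi) in enumerate(self.ranges):
            if self.lo_exclusive[i]:
                if lo < distance < hi:
                    return i
            elif lo <= distance < hi:
                return i
        return None


TWO_BIN = BinScheme("two_bin", ((0, 3), (3, 8)), (False, False))
THREE_BIN = BinScheme("three_bin", ((0, 2), (2, 5), (5, 8)), (True, False, False))


@dataclass(frozen=True)
class PharmacophoreFeature:
    """One detected feature: a family id and the atoms that carry it."""

    family: int
    member_atoms: frozenset[int]

    def __post_init__(self):
        if not self.member_atoms:
            raise ValueError("feature must cover at least one atom")
        if not 0 <= self.family < N_FAMILIES:
            raise ValueError(f"family id out of range: {self.family}")


@dataclass
class PharmacophoreGraph:
    """Detected features plus pairwise shortest topological distances."""

    features: list[PharmacophoreFeature]
    dist: np.ndarray  # (n, n) int matrix; >= MAX_DISTANCE means "too far"

    def __post_init__(self):
        n = len(self.features)
        self.dist = np.asarray(self.dist, dtype=np.int64)
        if self.dist.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.array_equal(self.dist, self.dist.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.dist) != 0):
            raise ValueError("self-distances must be zero")
        if np.any(self.dist < 0):
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class Fingerprint:
    """Binary pharmacophore fingerprint with its variant tag."""

    bits: np.ndarray
    variant: str  # P72 | P108 | P1032

    _LENGTHS = {"P72": 72, "P108": 108, "P1032": 1032}

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", bits)
        expected = self._LENGTHS.get(self.variant)
        if expected is None:
            raise ValueError(f"unknown variant {self.variant!r}")
        if bits.shape != (expected,):
            raise ValueError(f"{self.variant} requires {expected} bits, got {bits.shape}")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")

    def __len__(self) -> int:
        return len(self.bits)

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


# ---------------------------------------------------------------------------
# feature detection


def load_feature_definitions() -> list[tuple[int, str, "Chem.Mol"]]:
    """Parse the pinned SMARTS file into (family id, smarts, query) rows."""
    text = (
        resources.files("phoregen").joinpath("data/feature_definitions.smarts").read_text()
    )
    rows = []
    seen_families = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        family, smarts = line.split("\t")
        if family not in FAMILIES:
            raise ValueError(f"unknown feature family {family!r}")
        if family not in seen_families:
            seen_families.append(family)
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ValueError(f"bad SMARTS in feature definitions: {smarts}")
        rows.append((FAMILIES.index(family), smarts, query))
    if len(seen_families) != N_FAMILIES:
        raise ValueError(f"expected {N_FAMILIES} families, found {len(seen_families)}")
    return rows


_DEFINITIONS: list[tuple[int, str, "Chem.Mol"]] | None = None


def _definitions():
    global _DEFINITIONS
    if _DEFINITIONS is None:
        _DEFINITIONS = load_feature_definitions()
    return _DEFINITIONS


def parse_molecule(smiles: str) -> "Chem.Mol":
    """Parse and sanitize a SMILES string, rejecting invalid input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return mol


def detect_features(mol: "Chem.Mol") -> list[PharmacophoreFeature]:
    """Match every family SMARTS; dedup by (family, member atom set)."""
    seen: set[tuple[int, frozenset[int]]] = set()
    out: list[PharmacophoreFeature] = []
    for family, _smarts, query in _definitions():
        for match in mol.GetSubstructMatches(query):
            key = (family, frozenset(match))
            if key not in seen:
                seen.add(key)
                out.append(PharmacophoreFeature(family, key[1]))
    # deterministic order: by family, then sorted member atoms
    out.sort(key=lambda f: (f.family, tuple(sorted(f.member_atoms))))
    return out


def build_graph(mol: "Chem.Mol", features: list[PharmacophoreFeature]) -> PharmacophoreGraph:
    """Pairwise feature distances: min over member-atom pairs of the
    bond-count shortest path (closest-atom convention, so co-located
    features sit at distance 0).  Atoms in different connected components
    get a sentinel >= MAX_DISTANCE and therefore never set a bit.
    """
    n = len(features)
    dist = np.zeros((n, n), dtype=np.int64)
    if n == 0:
        return PharmacophoreGraph(features, dist)
    dmat = Chem.GetDistanceMatrix(mol)  # disconnected pairs come back huge
    sentinel = MAX_DISTANCE + 1
    members = [sorted(f.member_atoms) for f in features]
    for i in range(n):
        for j in range(i + 1, n):
            d = dmat[np.ix_(members[i], members[j])].min()
            d = sentinel if not np.isfinite(d) or d > MAX_DISTANCE else int(d)
            dist[i, j] = dist[j, i] = d
    return PharmacophoreGraph(features, dist)


# ---------------------------------------------------------------------------
# bit layouts


def pair_layout() -> list[tuple[int, int]]:
    """The 36 canonical family pairs (sorted id pairs) in layout order."""
    return list(itertools.combinations_with_replacement(range(N_FAMILIES), 2))


def triple_layout() -> list[tuple[int, int, int]]:
    """The 120 canonical family triples (sorted id multisets) in layout order."""
    return list(itertools.combinations_with_replacement(range(N_FAMILIES), 3))


_PAIR_INDEX = {pair: i for i, pair in enumerate(pair_layout())}
_TRIPLE_INDEX = {t: i for i, t in enumerate(triple_layout())}


def encode_two_point(graph: PharmacophoreGraph, scheme: BinScheme = TWO_BIN) -> Fingerprint:
    """Two-point fingerprint: bit (pair key, bin) is 1 if any pair of
    distinct feature instances of those families sits at a distance inside
    that bin.  Binary OR semantics; multiplicity is not recorded.
    """
    n_bins = scheme.n_bins
    bits = np.zeros(36 * n_bins, dtype=np.uint8)
    feats = graph.features
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            b = scheme.bin_index(int(graph.dist[i, j]))
            if b is None:
                continue
            key = tuple(sorted((feats[i].family, feats[j].family)))
            bits[_PAIR_INDEX[key] * n_bins + b] = 1
    variant = "P72" if n_bins == 2 else "P108"
    return Fingerprint(bits, variant)


def _canonical_triple(families: tuple[int, int, int], bins: tuple[int, int, int]):
    """Canonicalize a feature triple under permutation.

    The caller passes three features in arbitrary order plus the bins of
    the pairwise distances (0,1), (0,2), (1,2).  Every permutation that
    sorts the family ids ascending is tried and the lexicographically
    smallest (families, bin pattern) wins, which makes the encoding
    invariant to feature enumeration order even when families tie.
    """
    d = {(0, 1): bins[0], (1, 0): bins[0], (0, 2): bins[1], (2, 0): bins[1], (1, 2): bins[2], (2, 1): bins[2]}
    best = None
    for perm in itertools.permutations(range(3)):
        fams = tuple(families[p] for p in perm)
        if fams != tuple(sorted(fams)):
            continue
        pattern = (d[(perm[0], perm[1])], d[(perm[0], perm[2])], d[(perm[1], perm[2])])
        cand = (fams, pattern)
        if best is None or cand < best:
            best = cand
    assert best is not None
    return best


def encode_three_point(graph: PharmacophoreGraph) -> Fingerprint:
    """Combined two-point + three-point fingerprint under the 2-bin scheme.

    Layout: bits [0:72) are exactly ``encode_two_point(graph, TWO_BIN)``;
    bits [72:1032) cover the 120 canonical family triples x 8 bin patterns
    (the 3 pairwise distances each short/long, ordered lexicographically
    over the canonically ordered pairs).  A triple with any pairwise
    distance outside both bins contributes nothing.
    """
    two = encode_two_point(graph, TWO_BIN).bits
    bits = np.zeros(1032, dtype=np.uint8)
    bits[:72] = two
    feats = graph.features
    for i, j, k in itertools.combinations(range(len(feats)), 3):
        b_ij = TWO_BIN.bin_index(int(graph.dist[i, j]))
        b_ik = TWO_BIN.bin_index(int(graph.dist[i, k]))
        b_jk = TWO_BIN.bin_index(int(graph.dist[j, k]))
        if b_ij is None or b_ik is None or b_jk is None:
            continue
        fams = (feats[i].family, feats[j].family, feats[k].family)
        key, pattern = _canonical_triple(fams, (b_ij, b_ik, b_jk))
        pat_index = pattern[0] * 4 + pattern[1] * 2 + pattern[2]
        bits[72 + _TRIPLE_INDEX[key] * 8 + pat_index] = 1
    return Fingerprint(bits, "P1032")


def fingerprint(smiles: str, variant: str = "P72") -> Fingerprint:
    """Full pipeline: parse -> detect features -> graph -> encode."""
    mol = parse_molecule(smiles)
    graph = build_graph(mol, detect_features(mol))
    if variant == "P72":
        return encode_two_point(graph, TWO_BIN)
    if variant == "P108":
        return encode_two_point(graph, THREE_BIN)
    if variant == "P1032":
        return encode_three_point(graph)
    raise ValueError(f"unknown fingerprint variant {variant!r}")


def feature_counts(smiles: str) -> np.ndarray:
    """Per-family feature counts (length 8), the condition vector of the
    count-conditioned model and the n_j of the feature-count deviation."""
    mol = parse_molecule(smiles)
    counts = np.zeros(N_FAMILIES, dtype=np.int64)
    for f in detect_features(mol):
        counts[f.family] += 1
    return counts
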