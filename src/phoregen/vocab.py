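"""SMILES tokenization against a fixed chemical-language vocabulary.

The full vocabulary has 108 tokens (including the begin-of-sequence marker
'<'); pruning 14 infrequent bracket-atom tokens leaves the 94-token working
vocabulary.  Tokenization is greedy longest-match with a bracket-atom fast
path: '[' opens an atomic token that ends at the matching ']'.  Strings
containing substrings outside the vocabulary are rejected rather than
silently split.

A dedicated pad token is appended after the printed vocabulary for batching;
it doubles as the end-of-sequence symbol during generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

__all__ = [
    "BEGIN_TOKEN",
    "PAD_TOKEN",
    "Vocabulary",
    "TokenSequence",
    "TokenizationError",
    "canonical_vocab",
    "tokenize",
]

BEGIN_TOKEN = "<"
PAD_TOKEN = "<pad>"


class TokenizationError(ValueError):
    """An out-of-vocabulary substring, with its position."""

    def __init__(self, smiles: str, position: int, fragment: str):
        super().__init__(
            f"out-of-vocabulary substring {fragment!r} at position {position} in {smiles!r}"
        )
        self.smiles = smiles
        self.position = position
        self.fragment = fragment


@dataclass(frozen=True)
class TokenSequence:
    ids: tuple[int, ...]
    segment: tuple[int, ...]  # 0 = condition position, 1 = SMILES position

    def __post_init__(self):
        if len(self.ids) != len(self.segment):
            raise ValueError("ids and segment must have equal length")
        if any(s not in (0, 1) for s in self.segment):
            raise ValueError("segment labels must be 0/1")


class Vocabulary:
    """Ordered token list with encode/decode helpers."""

    def __init__(self, tokens: list[str]):
        if len(set(tokens)) != len(tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self.tokens = list(tokens)
        self.index = {t: i for i, t in enumerate(self.tokens)}
        if BEGIN_TOKEN not in self.index:
            raise ValueError("vocabulary must contain the begin token '<'")
        self.n_printed = len(self.tokens) - (1 if PAD_TOKEN in self.index else 0)
        if PAD_TOKEN not in self.index:
            self.tokens.append(PAD_TOKEN)
            self.index[PAD_TOKEN] = len(self.tokens) - 1
        # longest-match candidates, excluding specials never found in SMILES
        self._plain = sorted(
            (t for t in self.tokens if t not in (BEGIN_TOKEN, PAD_TOKEN) and not t.startswith("[")),
            key=len,
            reverse=True,
        )
        self._max_plain = max((len(t) for t in self._plain), default=1)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def begin_id(self) -> int:
        return self.index[BEGIN_TOKEN]

    @property
    def pad_id(self) -> int:
        return self.index[PAD_TOKEN]

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256("\n".join(self.tokens).encode()).hexdigest()

    # -- tokenize / encode / decode ------------------------------------

    def tokenize(self, smiles: str) -> list[str]:
        """Greedy longest-match segmentation; rejects OOV substrings."""
        out: list[str] = []
        i = 0
        n = len(smiles)
        while i < n:
            if smiles[i] == "[":
                j = smiles.find("]", i)
                if j < 0:
                    raise TokenizationError(smiles, i, smiles[i:])
                tok = smiles[i : j + 1]
                if tok not in self.index:
                    raise TokenizationError(smiles, i, tok)
                out.append(tok)
                i = j + 1
                continue
            for L in range(min(self._max_plain, n - i), 0, -1):
                tok = smiles[i : i + L]
                if tok in self.index:
                    out.append(tok)
                    i += L
                    break
            else:
                raise TokenizationError(smiles, i, smiles[i])
        return out

    def encode(self, smiles: str) -> TokenSequence:
        """Begin token + SMILES tokens as integer ids (all segment 1;
        condition positions are prepended by the model, not here)."""
        toks = self.tokenize(smiles)
        ids = (self.begin_id,) + tuple(self.index[t] for t in toks)
        return TokenSequence(ids, (1,) * len(ids))

    def decode(self, ids) -> str:
        """Inverse of encode: drop begin/pad, concatenate the rest."""
        parts = []
        for i in ids:
            t = self.tokens[int(i)]
            if t == BEGIN_TOKEN:
                continue
            if t == PAD_TOKEN:
                break
            parts.append(t)
        return "".join(parts)


def canonical_vocab(pruned: bool = True) -> Vocabulary:
    """The shipped vocabulary: full (108 tokens) or pruned (94 tokens),
    each with the pad token appended at the end."""
    name = "vocab_pruned.txt" if pruned else "vocab_full.txt"
    text = resources.files("phoregen").joinpath(f"data/{name}").read_text()
    tokens = [line for line in text.splitlines() if line]
    return Vocabulary(tokens)


def tokenize(smiles: str, vocabulary: Vocabulary | None = None) -> list[str]:
    """Module-level convenience wrapper around Vocabulary.tokenize."""
    if vocabulary is None:
        vocabulary = canonical_vocab(pruned=True)
    return vocabulary.tokenize(smiles)
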