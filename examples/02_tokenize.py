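"""Tokenize SMILES against the fixed chemical-language vocabulary.

The full vocabulary has 108 printed tokens; pruning 14 infrequent
bracket-atom tokens leaves 94.  Tokenization is greedy longest-match, so
'Br' and bracket atoms such as '[NH3+]' stay atomic.
"""

from phoregen import canonical_vocab
from phoregen.vocab import TokenizationError

full = canonical_vocab(pruned=False)
pruned = canonical_vocab(pruned=True)
print(f"printed vocabulary sizes: full={full.n_printed}, pruned={pruned.n_printed}")

for smi in ["CCO", "CCBr", "C[NH3+]C", "c1ccccc1"]:
    print(f"{smi!r} -> {pruned.tokenize(smi)}")

try:
    pruned.tokenize("CC[Se-]C")  # a pruned token
except TokenizationError as e:
    print("rejected:", e)
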