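# phoregen

Topological pharmacophore fingerprints and pharmacophore-conditioned
autoregressive SMILES generation, with the evaluation metrics and
screening procedures that go with them.

## Who this is for

Computational medicinal chemists and method developers who want a
scaffold-hopping generator: a model that, given only the *pharmacophore*
of a reference ligand (which chemical features it has and how many bonds
apart they sit), proposes molecules that preserve that feature arrangement
while being free to change the underlying chemical scaffold.

## The method

**Fingerprints.** A molecule is reduced to its pharmacophore features —
H-bond acceptors and donors, aromatic rings, positively/negatively
ionizable groups, hydrophobes, lumped (ring) hydrophobes and Zn binders,
eight families in all, matched by a pinned SMARTS definition file.  The
shortest bond-count path *d(i, j)* between every feature pair is
discretized into bins: the 2-bin scheme uses [0, 3) and [3, 8), the 3-bin
scheme (0, 2), [2, 5) and [5, 8); distances of 8 bonds or more are null
signals.  With 36 unordered family pairs this yields binary fingerprints
of length 36 × 2 = **72** and 36 × 3 = **108**; adding all 120 family
triples × 8 short/long bin patterns gives the combined two-+three-point
fingerprint of length 72 + 960 = **1032**.

**Model.**  A GPT-style causal transformer decoder (NumPy implementation)
receives the fingerprint as a prefix of learned value embeddings (segment
label 0) followed by the begin token and SMILES tokens (segment label 1),
with rotary positional encoding applied to attention queries and keys:
position *m* rotates each embedding pair (2i, 2i+1) by m·θ^(−2i/d), so
attention scores depend on relative positions only.  The training loss is
next-token cross-entropy over SMILES positions.  Sampling draws tokens
from softmax(logits / t) with temperature t = 0.7 by default; scaffold
elaboration forces a core fragment's tokens as the generation prefix.

**Metrics.**  S_struct is the Tanimoto coefficient of 2048-bit radius-2
Morgan fingerprints; S_pharma the Tanimoto of ErG fingerprints (both after
charge neutralization).  D_count = (1/N) Σᵢ Σⱼ |nⱼⁱ − nⱼʳᵉᶠ| is the mean
L1 deviation of per-family feature counts (m = 8 families).  Recall and
apparent precision quantify rediscovery of reserved actives; the
screening triage chains pharmacophore, drug-likeness, novelty, docking
and clustering filters and ranks by docking score and ligand efficiency
(docking score / molecular weight).

## Worked example

```python
import phoregen as pg
from phoregen import model as M

fp = pg.fingerprint("CC(=O)Oc1ccccc1C(=O)O", "P72")   # aspirin
print(len(fp), int(fp.bits.sum()))

vocab = pg.canonical_vocab(pruned=True)
corpus = [(s, f) for s, f, _ in pg.make_corpus(pg.ToyCorpusSpec(n_molecules=100, seed=7))]
cfg = M.ModelConfig(vocab_size=len(vocab), n_layers=2, n_heads=4, embed_dim=64,
                    feedforward_dim=256, max_seq_len=160,
                    condition_kind="fingerprint_72", seed=1)
state = M.train(corpus, cfg, vocab, n_epochs=300, batch_size=50, learning_rate=4e-3)
target, target_fp = corpus[0]
greedy = pg.sample(state, pg.GenerationRequest(n_samples=1, greedy=True),
                   vocab, condition=target_fp)[0]
print(target, "->", greedy)
```

prints

```
72 23
OC(=O)CCNCCCCSC -> OC(=O)CCNCCCCSC
```

The aspirin fingerprint has 72 bits with 23 set — one per (feature pair,
distance bin) present in the molecule.  After 300 epochs the toy decoder
has memorized the corpus, so greedy decoding under a training molecule's
fingerprint returns exactly that molecule: the condition channel, not the
token prior, is determining the output.  The `examples/` directory has one
short script per capability (fingerprints, tokenization, training and
sampling, scaffold elaboration, screening triage).

A thin CLI mirrors the library:
`phoregen fingerprint --variant 72 --in molecules.smi --out fp.csv`,
`phoregen sample`, `phoregen elaborate`, `phoregen evaluate`,
`phoregen screen`, `phoregen fixtures-make`, `phoregen vocab-check`.

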