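import numpy as np
import pytest
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # raw samples are often invalid; keep output clean

import phoregen as pg
from phoregen import model as M

# Study conditions of the desk-scale conditioning-recovery experiment:
# a 2-layer decoder trained on a 200-molecule synthetic corpus.
RECOVERY_CORPUS = pg.ToyCorpusSpec(n_molecules=200, seed=7)
RECOVERY_EPOCHS = 150
RECOVERY_BATCH = 50
RECOVERY_LR = 4e-3


def _model_config(condition_kind: str, vocab, seed: int = 1) -> M.ModelConfig:
    return M.ModelConfig(
        vocab_size=len(vocab),
        n_layers=2,
        n_heads=4,
        embed_dim=64,
        feedforward_dim=256,
        max_seq_len=160,
        condition_kind=condition_kind,
        seed=seed,
    )


@pytest.fixture(scope="session")
def vocab():
    return pg.canonical_vocab(pruned=True)


@pytest.fixture(scope="session")
def toy_corpus():
    """(smiles, P72 bits, counts) triples of the 200-molecule corpus."""
    return pg.make_corpus(RECOVERY_CORPUS)


@pytest.fixture(scope="session")
def conditional_model(vocab, toy_corpus):
    """Overfit 2-layer fingerprint-conditioned decoder (the heavy fixture)."""
    corpus = [(s, fp) for s, fp, _ in toy_corpus]
    cfg = _model_config("fingerprint_72", vocab)
    return M.train(corpus, cfg, vocab, n_epochs=RECOVERY_EPOCHS,
                   batch_size=RECOVERY_BATCH, learning_rate=RECOVERY_LR)


@pytest.fixture(scope="session")
def unconditional_model(vocab, toy_corpus):
    """Same architecture and corpus without the condition channel."""
    corpus = [(s, None) for s, _fp, _c in toy_corpus]
    cfg = _model_config("none", vocab)
    return M.train(corpus, cfg, vocab, n_epochs=RECOVERY_EPOCHS,
                   batch_size=RECOVERY_BATCH, learning_rate=RECOVERY_LR)


@pytest.fixture(scope="session")
def unique_fp_molecules(toy_corpus):
    """Corpus molecules whose P72 fingerprint is unique in the corpus, so
    the fingerprint-to-molecule mapping is well defined for them."""
    by_fp = {}
    for smi, fp, _c in toy_corpus:
        by_fp.setdefault(fp.tobytes(), []).append((smi, fp))
    return [v[0] for v in by_fp.values() if len(v) == 1]


@pytest.fixture(scope="session")
def worked():
    return pg.worked_molecules()
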