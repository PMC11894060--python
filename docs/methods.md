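# Methods

## Pharmacophore model

A molecule's pharmacophore is abstracted as a complete graph whose nodes
are feature instances from eight families — H-bond acceptor, H-bond
donor, aromatic ring, positively ionizable, negatively ionizable,
hydrophobe, lumped hydrophobe (whole ring systems acting as one
hydrophobic unit) and Zn binder — and whose edge weights are shortest
bond-count path distances.  Features are matched by a pinned SMARTS
definition file (`data/feature_definitions.smarts`), authored for this
package and fixed so that detected features cannot drift with toolkit
upgrades.  The family order in that file is the total order used for the
fingerprint bit layout.  Detection dedupes by (family, member-atom set):
a bit records presence, not multiplicity.

Distances between multi-atom features use the closest-atom convention:
d(i, j) = min over a ∈ atoms(i), b ∈ atoms(j) of the bond-graph shortest
path.  This keeps d = 0 possible for co-located features (ethanol's
hydroxyl is simultaneously donor and acceptor on the same oxygen) and is
the natural reading of "distance between feature pairs" when features
span several atoms.  Atoms in different connected components are beyond
every bin and therefore contribute null signals.

### Discretization and layout

* 2-bin scheme: short [0, 3), long [3, 8).
* 3-bin scheme: short (0, 2), medium [2, 5), long [5, 8).
* Distances ≥ 8 bonds never set a bit.

The 3-bin short range is implemented as the open interval (0, 2): a
co-located pair sets a short-bin bit under the 2-bin scheme but nothing
under the 3-bin scheme.  That asymmetry looks odd but is the published
definition of the scheme; we implement it as printed rather than guessing
an intended [0, 2).

Two-point layout: the 36 sorted family pairs in lexicographic order, n
bins per pair → lengths 72 and 108.  Three-point layout: the 120 sorted
family triples × 8 bin patterns appended after the 72-bit two-point
segment → 1032.  A triple is canonicalized by trying every feature
permutation whose family ids are non-decreasing and keeping the
lexicographically smallest (families, bin-pattern) — this makes the
encoding invariant to feature enumeration order, including ties where two
or three features share a family.  The first 72 bits of the 1032-bit
variant are bit-for-bit the 72-bit fingerprint.

## Vocabulary and tokenization

The full 108-token vocabulary (including the begin marker `<`) and the
pruned 94-token vocabulary (14 infrequent bracket-atom tokens removed)
are shipped verbatim as one-token-per-line files.  Tokenization is greedy
longest-match with a bracket fast path (`[` … `]` is one atomic token);
out-of-vocabulary input is rejected with the offending substring and
position rather than silently decomposed.  The vocabulary files do not
state an end-of-sequence convention, so a dedicated `<pad>` token is
appended after the printed list; it doubles as end-of-sequence — the
model is trained to emit it after the last SMILES token and sampling
stops on it.

## Decoder

A causal transformer decoder implemented in NumPy (forward, hand-written
backpropagation, Adam).  Inputs are laid out as [condition prefix][`<`]
[SMILES tokens]: each condition entry (fingerprint bit, or feature count
clipped at 15) contributes one prefix position embedded as value
embedding + condition-position embedding; segment embeddings (0 =
condition, 1 = SMILES) distinguish the channels.  Rotary positional
encoding is applied to attention queries and keys: dimension pairs
(2i, 2i+1) rotate by m·θ^(−2i/d) at position m (θ = 10000), which makes
rotated inner products depend only on relative position — verified
numerically in the tests.

The attention blocks use standard softmax causal attention.  The
linear-attention formulation with non-negative feature maps, under which
rotary encoding was originally motivated, is not implemented: the
relative-position property of the rotation holds under both forms, and
softmax is the GPT default this decoder otherwise follows.  The config
validates `attention="softmax"` so the choice is explicit and a second
kernel could be added behind the same field.

Training minimizes next-token cross-entropy on SMILES positions only
(condition positions and post-end padding are masked; exactly one pad
token per sequence is a real end-of-sequence target).  All randomness —
initialization, batch shuffling, dropout — derives from the config seed,
so training is bit-reproducible.  The default learning-rate schedule is
cosine decay to 10% of the base rate, which noticeably sharpens
memorization on small corpora; a constant schedule is available.

Default desk-scale configuration: 2 layers, 4 heads, embedding 64, MLP
256, float32.  A full-size configuration is a ModelConfig away but is not
exercised by the test suite.  Optimizer defaults (Adam, lr 3e-3, batch
32) are package choices; nothing here claims to match any published
hyperparameter table.

## Generation

Sampling draws tokens from softmax(logits / t); t = 0.7 is the default,
matching the low-temperature screening protocol, and a greedy flag gives
the argmax decode.  Generation stops at the pad/end token or at
max_length; unterminated strings go to postprocessing as-is, where
unparseable strings are dropped and survivors canonicalized and deduped.

Scaffold elaboration fragments a conditioning compound by cutting one
random acyclic single bond between heavy atoms (never ring bonds, never
bonds to hydrogen).  One fragment becomes the core (generation prefix),
the other the reference whose fingerprint is the condition.  The core is
written as a rooted SMILES whose attachment atom is the final written
atom, so appending generated tokens extends the molecule from the cut
point; the root is found by scanning candidate root atoms for a traversal
ending at the attachment atom (for rare branched attachments where no
traversal ends there, the core falls back to being rooted at the
attachment atom).  How the original protocol primes its decoder with a
core is unstated; this rooting convention is this package's documented
choice, made so that core + completion is a single valid SMILES.

## Metrics

* S_struct: Tanimoto of 2048-bit radius-2 Morgan fingerprints.
* S_pharma: Tanimoto of ErG fingerprints.  ErG vectors are non-negative
  reals, so the continuous Tanimoto a·b / (|a|² + |b|² − a·b) is used; it
  reduces to the binary form on 0/1 vectors and is 1 iff the vectors are
  equal.
* Both are computed after charge neutralization: protonated centers with
  a removable proton and deprotonated centers that can accept one are
  returned to neutral form atom by atom; quaternary ammonium and other
  non-neutralizable charges are left untouched.  The neutralization rule
  set is a package choice (the step is standard, its rules are not
  published); exact-recall matching is performed after neutralization.
* D_count: mean L1 distance between 8-long feature-count vectors of
  generated molecules and the reference.
* Recall: fraction of reserved actives whose neutralized canonical SMILES
  appears in the generated set; relaxed mode also accepts a generated
  molecule with S_struct ≥ 0.8 to the active.
* Apparent precision: molecules sampled more than once join a
  high-confidence set in order of first repeat until a budget of 4000;
  the count of reserved actives matched within that set is reported.

## Screening procedures

The scaffold-clustered split extracts Bemis-Murcko scaffolds, clusters
them with Butina sphere exclusion (Morgan r2/2048, distance threshold
0.4), sorts clusters by member count descending (ties by canonical
scaffold string), and sends 1-based odd-indexed clusters to training,
even-indexed to the heldout set.  "Odd-indexed" is read as 1-based — the
largest cluster trains — and is switchable (`odd_to_train=False`).

The triage pipeline applies, in order: pharmacophoric similarity to the
reference ≥ 0.85; Lipinski's rule of five with the molecular-weight cap
raised to 1000 Da plus a pinned structural-alert SMARTS list
(`data/structural_alerts.smarts`, a compact standard medicinal-chemistry
alert set authored for this package); a novelty SMARTS filter (default
pattern excludes close analogues of the reference's fused core); docking
score ≤ −9.0 kcal/mol ("better than" = more negative) with ≥ 2 key-residue
polar contacts of which Cys133 is requisite; scaffold grouping plus
Butina clustering of scaffolds at distance 0.1; one representative per
cluster by best docking score then ligand efficiency; final ranking by
(docking score, ligand efficiency) with canonical-SMILES tie-break
everywhere for determinism.  Ligand efficiency is docking score divided
by molecular weight — deliberately the protocol's definition, not the
conventional per-heavy-atom form.  Docking scores and interaction flags
are consumed from external tools; producing them is out of scope.

## Synthetic corpora

The fixtures module assembles molecules from pre-validated building
blocks (hydroxyl, amine, amide, carboxylic acid, nitrile, phenyl,
thioether) joined by alkyl linkers of 1-6 carbons, so pairwise feature
distances sweep both 2-bin ranges.  Generation is a pure function of
(n_molecules, seed, linker range): the block grid is enumerated, deduped
by canonical SMILES, seeded-shuffled and truncated.  Every molecule is
checked to parse and tokenize.  The default spec (200 molecules, seed 7)
defines the corpus used by the conditioning-recovery experiment.

What these corpora emulate: controllable pharmacophore content, fixed
vocabulary coverage, distances straddling the bin boundary.  What they do
not: the size, property distributions, stereochemistry, and scaffold
diversity of real screening libraries.  Passing the toy-scale tests shows
the machinery is correct and that the condition channel steers
generation; it does not certify generative quality on real chemistry.

## Desk-scale experiment sizes

The conditioning-recovery experiment trains the 2-layer, 64-dim decoder
on the 200-molecule corpus for 150 epochs (batch 50, lr 4e-3, cosine),
and an unconditional twin on the same molecules; sampling uses 8 samples
per seed over 20 seeds at t = 0.7.  These sizes were chosen so the whole
experiment runs in minutes on one CPU core while still exhibiting the
memorization and conditioning-gap behavior the tests assert.

## Known limitations and out-of-scope reference points

* Single-CPU NumPy training limits corpora to the thousands; no GPU path.
* The SMARTS feature definitions are compact, not exhaustive; family
  coverage on exotic chemotypes will differ from richer definition sets.
* Fragment linking, SELFIES, SMILES augmentation, 3D pharmacophores and
  conformer generation are not implemented.
* Full-scale results — benchmark similarity scores from
  million-molecule training, active-recall percentages against external
  activity databases, predicted-active fractions from external QSAR
  models, unique-molecule counts from million-sample runs, and all
  experimental IC50 values — require resources outside this package.
  They are recorded as documentation-only constants in
  `phoregen.reference` with the reason each is out of reach, and no code
  here computes or asserts them.
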