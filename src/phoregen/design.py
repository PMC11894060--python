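"""Case-study procedures: scaffold-clustered splitting and screening triage.

Two computable workflows sit here.  The first is the scaffold-disjoint
train/heldout split used for active-recall experiments: Bemis-Murcko
scaffolds are extracted, Butina-clustered on Morgan fingerprints
(distance threshold 0.4), clusters sorted by size, and molecules in the
1-based odd-indexed clusters go to training while even-indexed clusters
are reserved for rediscovery.  The second is the post-generation triage
pipeline over externally supplied docking results: pharmacophoric
similarity gate, drug-likeness and structural-alert filters, a novelty
SMARTS filter, docking-score and key-residue interaction gates, scaffold
grouping plus Butina clustering, per-cluster representative selection, and
final ranking by docking score and ligand efficiency (docking score
divided by molecular weight).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .features import parse_molecule
from .metrics import s_pharma

__all__ = [
    "TriageConfig",
    "TriageResult",
    "bemis_murcko",
    "butina_cluster",
    "drd2_split",
    "load_structural_alerts",
    "triage",
]

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

#: Novelty filter excluding close analogues of the reference scaffold
#: (a fused bicyclic core linked through a two-carbon bridge to an azole).
DEFAULT_NOVELTY_SMARTS = "c12ncncc1-CC-[n,c]3:[n,c]:[n,c]:[n,c]:[n,c]32"


def bemis_murcko(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold (ring systems plus linkers).

    Acyclic molecules have no scaffold and yield the empty string.
    """
    mol = parse_molecule(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def butina_cluster(fingerprints, distance_threshold: float) -> list[list[int]]:
    """Sphere-exclusion (Butina) clustering on Tanimoto distances.

    Centroid candidates are processed in order of decreasing neighbor
    count (ties by lower index, so pre-sorting the items fixes the
    tie-break); each centroid claims every unassigned item within
    ``distance_threshold``.  Returns disjoint, exhaustive clusters as
    index lists, centroid first.
    """
    n = len(fingerprints)
    if n == 0:
        raise ValueError("empty input")
    neighbors = [[] for _ in range(n)]
    for i in range(n):
        if i + 1 < n:
            sims = DataStructs.BulkTanimotoSimilarity(fingerprints[i], list(fingerprints[i + 1 :]))
            for off, s in enumerate(sims):
                j = i + 1 + off
                if 1.0 - s <= distance_threshold:
                    neighbors[i].append(j)
                    neighbors[j].append(i)
    order = sorted(range(n), key=lambda i: (-len(neighbors[i]), i))
    assigned = np.zeros(n, dtype=bool)
    clusters: list[list[int]] = []
    for c in order:
        if assigned[c]:
            continue
        members = [c] + [j for j in sorted(neighbors[c]) if not assigned[j]]
        for m in members:
            assigned[m] = True
        clusters.append(members)
    return clusters


def _scaffold_fp(scaffold_smiles: str):
    mol = Chem.MolFromSmiles(scaffold_smiles) if scaffold_smiles else Chem.MolFromSmiles("")
    if mol is None:
        mol = Chem.MolFromSmiles("")
    return _MORGAN.GetFingerprint(mol)


def drd2_split(actives: list[str], distance_threshold: float = 0.4,
               odd_to_train: bool = True) -> tuple[list[str], list[str]]:
    """Scaffold-clustered partition of active ligands.

    Scaffolds are clustered with Butina at ``distance_threshold``; clusters
    are sorted by member count descending (ties by canonical scaffold
    string), and molecules whose scaffolds sit in 1-based odd-indexed
    clusters go to training, even-indexed to the heldout set.  The split is
    scaffold-disjoint by construction.
    """
    scaffolds = [bemis_murcko(s) for s in actives]
    unique = sorted(set(scaffolds))
    if len(unique) < 2:
        raise ValueError("need at least two distinct scaffolds to split")
    fps = [_scaffold_fp(s) for s in unique]
    clusters = butina_cluster(fps, distance_threshold)
    by_scaffold: dict[str, int] = {}
    sized = []
    for ci, members in enumerate(clusters):
        scafs = [unique[m] for m in members]
        size = sum(scaffolds.count(s) for s in scafs)
        sized.append((size, tuple(sorted(scafs)), scafs))
    sized.sort(key=lambda t: (-t[0], t[1]))
    train, heldout = [], []
    for rank, (_size, _key, scafs) in enumerate(sized, start=1):
        odd = rank % 2 == 1
        to_train = odd if odd_to_train else not odd
        for s in scafs:
            by_scaffold[s] = to_train
    for smi, scaf in zip(actives, scaffolds):
        (train if by_scaffold[scaf] else heldout).append(smi)
    return train, heldout


# ---------------------------------------------------------------------------
# triage


@dataclass
class TriageConfig:
    """Thresholds of the screening triage; defaults follow the published
    screening protocol ("better than -9.0 kcal/mol" means more negative)."""

    pharma_min: float = 0.85
    mw_max: float = 1000.0
    novelty_smarts: tuple[str, ...] = (DEFAULT_NOVELTY_SMARTS,)
    score_max: float = -9.0
    required_residue: str = "Cys133"
    min_polar_contacts: int = 2
    butina_threshold: float = 0.1
    keep_n: int = 2300
    apply_alerts: bool = True


@dataclass
class TriageResult:
    table: pd.DataFrame           # every record with per-stage pass flags
    survivors: pd.DataFrame       # ranked survivors
    stage_counts: dict = field(default_factory=dict)


def load_structural_alerts() -> list[tuple[str, "Chem.Mol"]]:
    text = resources.files("phoregen").joinpath("data/structural_alerts.smarts").read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split("\t")
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            raise ValueError(f"bad alert SMARTS {smarts!r}")
        out.append((name, q))
    return out


def _druglike(mol, mw_max: float, alerts) -> bool:
    """Lipinski's rule of five with the molecular-weight cap raised to
    ``mw_max``, plus structural-alert rejection."""
    if Descriptors.MolWt(mol) > mw_max:
        return False
    if Lipinski.NumHDonors(mol) > 5 or Lipinski.NumHAcceptors(mol) > 10:
        return False
    if Crippen.MolLogP(mol) > 5:
        return False
    for _name, q in alerts:
        if mol.HasSubstructMatch(q):
            return False
    return True


def _parse_interactions(value) -> set[str]:
    if isinstance(value, (set, frozenset, list, tuple)):
        return {str(v) for v in value if str(v)}
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return set()
    return {p.strip() for p in str(value).split(";") if p.strip()}


def triage(records: pd.DataFrame, reference_smiles: str,
           config: TriageConfig | None = None) -> TriageResult:
    """Run the staged screening triage over scored generation records.

    ``records`` needs columns ``smiles``, ``docking_score`` and
    ``interactions`` (semicolon-separated residue tags); a precomputed
    ``s_pharma_to_ref`` column is used when present.  Stages only ever
    shrink the candidate set; per-stage pass flags and counts are returned
    alongside the ranked survivors.
    """
    cfg = config or TriageConfig()
    df = records.copy().reset_index(drop=True)
    alerts = load_structural_alerts() if cfg.apply_alerts else []
    novelty = [Chem.MolFromSmarts(s) for s in cfg.novelty_smarts]
    if any(q is None for q in novelty):
        raise ValueError("bad novelty SMARTS pattern")

    mols, valid = [], []
    for smi in df["smiles"]:
        mol = Chem.MolFromSmiles(str(smi))
        mols.append(mol)
        valid.append(mol is not None)
    df["valid"] = valid

    if "s_pharma_to_ref" not in df.columns:
        df["s_pharma_to_ref"] = [
            s_pharma(str(smi), reference_smiles) if ok else np.nan
            for smi, ok in zip(df["smiles"], valid)
        ]
    df["mol_weight"] = [Descriptors.MolWt(m) if m is not None else np.nan for m in mols]

    missing_score = df["docking_score"].isna()
    if missing_score.any():
        warnings.warn(f"{int(missing_score.sum())} records lack a docking score; skipped")

    df["pass_pharma"] = df["valid"] & (df["s_pharma_to_ref"] >= cfg.pharma_min)
    df["pass_druglike"] = df["pass_pharma"] & np.array(
        [bool(ok and _druglike(m, cfg.mw_max, alerts))
         for ok, m in zip(df["pass_pharma"], mols)]
    )
    df["pass_novelty"] = df["pass_druglike"] & np.array(
        [bool(ok and m is not None and not any(m.HasSubstructMatch(q) for q in novelty))
         for ok, m in zip(df["pass_druglike"], mols)]
    )
    inter = [_parse_interactions(v) for v in df["interactions"]]
    df["pass_docking"] = (
        df["pass_novelty"]
        & ~missing_score
        & (df["docking_score"] <= cfg.score_max)
        & np.array([len(s) >= cfg.min_polar_contacts and cfg.required_residue in s
                    for s in inter])
    )
    df["ligand_efficiency"] = df["docking_score"] / df["mol_weight"]

    # scaffold grouping + Butina clustering of the scaffolds
    cand = df[df["pass_docking"]].copy()
    cand["canonical"] = [Chem.MolToSmiles(mols[i]) for i in cand.index]
    cand["scaffold"] = [bemis_murcko(s) for s in cand["canonical"]]
    df["pass_cluster"] = False
    df["rank"] = np.nan
    survivors = cand.iloc[0:0]
    if len(cand):
        unique_scaffolds = sorted(cand["scaffold"].unique())
        fps = [_scaffold_fp(s) for s in unique_scaffolds]
        clusters = butina_cluster(fps, cfg.butina_threshold)
        reps = []
        for members in clusters:
            scafs = {unique_scaffolds[m] for m in members}
            group = cand[cand["scaffold"].isin(scafs)]
            # best member: lowest docking score, then ligand efficiency,
            # then canonical SMILES for determinism
            group = group.sort_values(
                ["docking_score", "ligand_efficiency", "canonical"]
            )
            reps.append(group.index[0])
        df.loc[reps, "pass_cluster"] = True
        survivors = df.loc[reps].copy()
        survivors["canonical"] = cand.loc[reps, "canonical"]
        survivors = survivors.sort_values(
            ["docking_score", "ligand_efficiency", "canonical"]
        ).head(cfg.keep_n)
        survivors["rank"] = np.arange(1.0, len(survivors) + 1)
        df.loc[survivors.index, "rank"] = survivors["rank"]

    counts = {
        "input": len(df),
        "pharma": int(df["pass_pharma"].sum()),
        "druglike": int(df["pass_druglike"].sum()),
        "novelty": int(df["pass_novelty"].sum()),
        "docking": int(df["pass_docking"].sum()),
        "cluster_representatives": int(df["pass_cluster"].sum()),
        "ranked": len(survivors),
    }
    return TriageResult(table=df, survivors=survivors.reset_index(drop=True),
                        stage_counts=counts)
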