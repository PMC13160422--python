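"""Four-stage virtual-screening cascade and nearest-reference analysis.

Stage 1 removes invalid molecules and rule-of-five violators; stage 2 keeps
molecules whose Murcko scaffold is Tanimoto-similar (ECFP4, >= 0.50 by
default) to at least one reference-inhibitor scaffold; stage 3 ranks the
survivors by high QED and low synthetic-accessibility score and keeps the
top fraction; stage 4 picks diverse representatives by Butina
sphere-exclusion clustering on whole-molecule fingerprints. Each selected
representative is finally categorized against the reference set as
high-fidelity (HF, best Tanimoto >= 0.70), scaffold-hopping (SH, in
[0.50, 0.70)) or other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from rdkit import Chem, DataStructs

from .metrics import fingerprint, murcko_scaffold, property_profile
from .model import ConfigError

logger = logging.getLogger(__name__)

HF_THRESHOLD = 0.70
SH_THRESHOLD = 0.50


@dataclass
class ScreeningConfig:
    max_ro5_violations: int = 1
    scaffold_threshold: float = 0.50
    top_fraction: float = 0.25
    butina_cutoff: float = 0.6     # Tanimoto *distance* cutoff
    per_cluster: int = 1


@dataclass
class ScreeningReport:
    input_count: int
    stage1_survivors: list[str]
    stage2_survivors: list[str]
    stage3_pool: list[str]
    representatives: list[str]
    clusters: list[list[int]]
    categories: list[dict]
    config: dict = field(default_factory=dict)

    @property
    def stage_counts(self) -> dict[str, int]:
        return {"input": self.input_count,
                "stage1": len(self.stage1_survivors),
                "stage2": len(self.stage2_survivors),
                "stage3": len(self.stage3_pool),
                "stage4": len(self.representatives)}

    def as_dict(self) -> dict:
        d = asdict(self)
        d["stage_counts"] = self.stage_counts
        return d


# ------------------------------------------------------------------- stage 1
def lipinski_filter(molecules: list[str], max_violations: int = 1) -> list[str]:
    """Keep valid molecules with at most *max_violations* among
    {MW > 500, LogP > 5, HBD > 5, HBA > 10}."""
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
    out = []
    for s in molecules:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        violations = sum([
            Descriptors.MolWt(mol) > 500,
            Crippen.MolLogP(mol) > 5,
            rdMolDescriptors.CalcNumHBD(mol) > 5,
            rdMolDescriptors.CalcNumHBA(mol) > 10,
        ])
        if violations <= max_violations:
            out.append(Chem.MolToSmiles(mol))
    return out


# ------------------------------------------------------------------- stage 2
def _scaffold_fp(smiles: str):
    scaf = murcko_scaffold(smiles)
    if not scaf:
        return None
    return fingerprint(Chem.MolFromSmiles(scaf))


def scaffold_filter(molecules: list[str], refs: list[str],
                    threshold: float = 0.50) -> list[str]:
    """Keep molecules whose Murcko-scaffold fingerprint reaches Tanimoto
    >= *threshold* (inclusive) to at least one reference scaffold; acyclic
    molecules are removed with a log entry."""
    if not refs:
        raise ValueError("scaffold_filter needs a non-empty reference set")
    ref_fps = [fp for fp in (_scaffold_fp(r) for r in refs) if fp is not None]
    if not ref_fps:
        raise ConfigError("all reference molecules are acyclic: no scaffolds")
    out = []
    for s in molecules:
        fp = _scaffold_fp(s)
        if fp is None:
            logger.info("stage 2: removing acyclic molecule %s", s)
            continue
        if max(DataStructs.BulkTanimotoSimilarity(fp, ref_fps)) >= threshold:
            out.append(s)
    return out


# ------------------------------------------------------------------- stage 3
def rank_pool(molecules: list[str], top_fraction: float = 0.25) -> list[str]:
    """Rank by composite rank(QED desc) + rank(SA asc), ties broken by
    canonical SMILES, and keep the top fraction (at least one molecule)."""
    if not molecules:
        raise ValueError("rank_pool received an empty pool")
    prof = property_profile(molecules)
    smiles = prof["smiles"].tolist()
    qed_rank = (-prof["QED"]).rank(method="min")
    sa_rank = prof["SA"].rank(method="min")
    composite = (qed_rank + sa_rank).tolist()
    order = sorted(range(len(smiles)), key=lambda i: (composite[i], smiles[i]))
    keep = max(1, math.ceil(top_fraction * len(order)))
    return [smiles[i] for i in order[:keep]]


# ------------------------------------------------------------------- stage 4
def butina_cluster(fps, distance_cutoff: float) -> list[list[int]]:
    """Sphere-exclusion (Butina) clustering on Tanimoto distance.

    Neighbourhoods are all points within *distance_cutoff* of a point
    (inclusive). Candidate centroids are processed in order of decreasing
    neighbour count, ties broken by lowest index; each centroid claims its
    still-unassigned neighbours. Every cluster lists its centroid first.
    """
    n = len(fps)
    sim_thresh = 1.0 - distance_cutoff
    neighbors = []
    for i in range(n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps)
        neighbors.append([j for j, s in enumerate(sims) if s >= sim_thresh])
    order = sorted(range(n), key=lambda i: (-len(neighbors[i]), i))
    assigned = np.zeros(n, dtype=bool)
    clusters: list[list[int]] = []
    for c in order:
        if assigned[c]:
            continue
        members = [c] + [j for j in neighbors[c] if not assigned[j] and j != c]
        for j in members:
            assigned[j] = True
        clusters.append(members)
    return clusters


def butina_select(pool: list[str], distance_cutoff: float = 0.6,
                  per_cluster: int = 1) -> tuple[list[str], list[list[int]]]:
    """Cluster the ranked pool and pick the best-ranked member(s) per cluster.

    The pool is assumed ordered by stage-3 rank, so the best-ranked member of
    a cluster is the one with the lowest pool index.
    """
    if not pool:
        raise ValueError("butina_select received an empty pool")
    mols = [Chem.MolFromSmiles(s) for s in pool]
    fps = [fingerprint(m) for m in mols]
    clusters = butina_cluster(fps, distance_cutoff)
    reps: list[str] = []
    for members in clusters:
        best = sorted(members)[:per_cluster]
        reps.extend(pool[i] for i in best)
    return reps, clusters


# ----------------------------------------------------------- categorization
def categorize_vs_reference(candidates: list[str], refs: list[str]
                            ) -> list[dict]:
    """Best whole-molecule Tanimoto to the references plus an HF/SH/other
    call (HF >= 0.70, SH in [0.50, 0.70), other < 0.50)."""
    if not refs:
        raise ValueError("categorize_vs_reference needs references")
    ref_fps = [fingerprint(Chem.MolFromSmiles(r)) for r in refs
               if Chem.MolFromSmiles(r) is not None]
    out = []
    for s in candidates:
        mol = Chem.MolFromSmiles(s)
        best = max(DataStructs.BulkTanimotoSimilarity(fingerprint(mol), ref_fps))
        if best >= HF_THRESHOLD:
            cat = "HF"
        elif best >= SH_THRESHOLD:
            cat = "SH"
        else:
            cat = "other"
        out.append({"smiles": s, "best_similarity": float(best), "category": cat})
    return out


# ----------------------------------------------------------------- cascade
def run_cascade(gen: list[str], refs: list[str],
                config: ScreeningConfig | None = None) -> ScreeningReport:
    """Compose the four stages in order; survivor sets are nested and the
    whole cascade is deterministic."""
    if not gen or not refs:
        raise ValueError("run_cascade needs non-empty inputs")
    cfg = config or ScreeningConfig()
    s1 = lipinski_filter(gen, cfg.max_ro5_violations)
    s2 = scaffold_filter(s1, refs, cfg.scaffold_threshold)
    s3 = rank_pool(s2, cfg.top_fraction) if s2 else []
    reps, clusters = butina_select(s3, cfg.butina_cutoff, cfg.per_cluster) \
        if s3 else ([], [])
    for smaller, larger in (((reps), set(s3)), (set(s3), set(s2)),
                            (set(s2), set(s1))):
        assert set(smaller) <= set(larger), "survivor sets must be nested"
    cats = categorize_vs_reference(reps, refs) if reps else []
    return ScreeningReport(
        input_count=len(gen), stage1_survivors=s1, stage2_survivors=s2,
        stage3_pool=s3, representatives=reps, clusters=clusters,
        categories=cats, config=asdict(cfg))
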