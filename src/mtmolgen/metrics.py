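"""Generative metric suite, physicochemical profiling and scaffold census.

The metric definitions follow the community-standard generative-chemistry
benchmark conventions: validity / uniqueness / novelty over canonical
SMILES, internal diversity as one minus mean pairwise Tanimoto on 2048-bit
radius-2 circular fingerprints, similarity-to-nearest-neighbour (SNN),
cosine similarity of BRICS-fragment and Murcko-scaffold frequency vectors,
and a Fréchet distance between Gaussians fitted to feature vectors of the
generated and reference sets. The default Fréchet featurizer is a built-in
standardized physicochemical descriptor block (self-contained, no
downloads); a neural ``chemnet`` featurizer can be plugged in via
``register_featurizer`` where such weights are locally available.
"""

from __future__ import annotations

import logging
import sys
import os
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.linalg
from rdkit import Chem
from rdkit.Chem import BRICS, Crippen, Descriptors, QED, RDConfig, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit import DataStructs

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, Ertl-Schuffenhauer SA score)

logger = logging.getLogger(__name__)

#: package-wide fingerprint convention: circular, radius 2, 2048 bits (ECFP4)
_FPGEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def fingerprint(mol: Chem.Mol):
    return _FPGEN.GetFingerprint(mol)


def _mols(smiles: list[str]) -> list[Chem.Mol]:
    return [m for m in (Chem.MolFromSmiles(s) for s in smiles) if m is not None]


# ----------------------------------------------------------- basic fractions
def validity(gen: list[str]) -> float:
    """Fraction of parseable SMILES; duplicates count per occurrence."""
    if len(gen) == 0:
        raise ValueError("validity of an empty set is undefined")
    return sum(Chem.MolFromSmiles(s) is not None for s in gen) / len(gen)


def canonical_set(smiles: list[str]) -> list[str]:
    """Canonical forms of the valid molecules, in input order with duplicates."""
    out = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            out.append(Chem.MolToSmiles(mol))
    return out


def uniqueness(gen: list[str]) -> float:
    """|unique canonical| / |valid|."""
    valid = canonical_set(gen)
    if not valid:
        raise ValueError("no valid molecules")
    return len(set(valid)) / len(valid)


def novelty(gen: list[str], train: list[str]) -> float:
    """Fraction of unique generated canonicals absent from the training set."""
    unique = set(canonical_set(gen))
    if not unique:
        raise ValueError("no valid molecules")
    train_canon = set(canonical_set(train))
    return len(unique - train_canon) / len(unique)


# -------------------------------------------------------- fingerprint metrics
def int_div(gen: list[str]) -> float:
    """Internal diversity: 1 − mean pairwise Tanimoto over ordered pairs i≠j."""
    mols = _mols(gen)
    if len(mols) < 2:
        raise ValueError("internal diversity needs >= 2 valid molecules")
    fps = [fingerprint(m) for m in mols]
    n = len(fps)
    total = 0.0
    for i in range(n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        total += 2.0 * sum(sims)     # (i,j) and (j,i)
    return 1.0 - total / (n * (n - 1))


def snn(gen: list[str], ref: list[str]) -> float:
    """Mean over generated molecules of the max Tanimoto to the reference set."""
    gm, rm = _mols(gen), _mols(ref)
    if not gm or not rm:
        raise ValueError("snn needs non-empty valid sets")
    ref_fps = [fingerprint(m) for m in rm]
    vals = [max(DataStructs.BulkTanimotoSimilarity(fingerprint(m), ref_fps))
            for m in gm]
    return float(np.mean(vals))


# ----------------------------------------------------- frequency-vector sims
def _cosine(a: Counter, b: Counter) -> float:
    keys = set(a) | set(b)
    va = np.array([a.get(k, 0) for k in keys], dtype=float)
    vb = np.array([b.get(k, 0) for k in keys], dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("empty frequency vector")
    return float(va @ vb / (na * nb))


def _fragment_counts(smiles: list[str]) -> Counter:
    counts: Counter = Counter()
    for m in _mols(smiles):
        try:
            frags = BRICS.BRICSDecompose(m)
        except Exception:     # pragma: no cover - RDKit internal failures
            continue
        counts.update(frags)
    return counts


def _scaffold_counts(smiles: list[str]) -> Counter:
    counts: Counter = Counter()
    for m in _mols(smiles):
        scaf = MurckoScaffold.MurckoScaffoldSmiles(mol=m)
        if scaf:
            counts[scaf] += 1
    return counts


def frag_sim(gen: list[str], ref: list[str]) -> float | None:
    """Cosine similarity of BRICS-fragment frequency vectors; ``None`` when
    either side yields no fragments (logged)."""
    a, b = _fragment_counts(gen), _fragment_counts(ref)
    if not a or not b:
        logger.warning("frag_sim undefined: a set produced no fragments")
        return None
    return _cosine(a, b)


def scaff_sim(gen: list[str], ref: list[str]) -> float | None:
    """Cosine similarity of Murcko-scaffold frequency vectors."""
    a, b = _scaffold_counts(gen), _scaffold_counts(ref)
    if not a or not b:
        logger.warning("scaff_sim undefined: a set produced no scaffolds")
        return None
    return _cosine(a, b)


# ----------------------------------------------------------- Frechet distance
_DESCRIPTOR_FNS = [
    ("MW", Descriptors.MolWt),
    ("LogP", Crippen.MolLogP),
    ("TPSA", rdMolDescriptors.CalcTPSA),
    ("HBD", rdMolDescriptors.CalcNumHBD),
    ("HBA", rdMolDescriptors.CalcNumHBA),
    ("RotB", rdMolDescriptors.CalcNumRotatableBonds),
    ("Rings", rdMolDescriptors.CalcNumRings),
    ("FracCSP3", rdMolDescriptors.CalcFractionCSP3),
    ("QED", QED.qed),
    ("SA", sascorer.calculateScore),
]

_FEATURIZERS: dict[str, callable] = {}


def register_featurizer(name: str, fn) -> None:
    """Register an alternative featurizer (e.g. a local ChemNet)."""
    _FEATURIZERS[name] = fn


def descriptor_features(smiles: list[str]) -> np.ndarray:
    """Fixed physicochemical descriptor block, one row per valid molecule."""
    rows = [[fn(m) for _, fn in _DESCRIPTOR_FNS] for m in _mols(smiles)]
    return np.asarray(rows, dtype=float)


def frechet_gaussian(mu1: np.ndarray, cov1: np.ndarray,
                     mu2: np.ndarray, cov2: np.ndarray,
                     eps: float = 1e-8) -> float:
    """Fréchet distance between two Gaussians:
    ``|mu1-mu2|^2 + Tr(C1 + C2 - 2 (C1 C2)^{1/2})``.

    Near-singular covariances are regularized by flooring eigenvalues at
    *eps* (logged when it changes anything).
    """
    mu1, mu2 = np.atleast_1d(mu1).astype(float), np.atleast_1d(mu2).astype(float)
    cov1, cov2 = np.atleast_2d(cov1).astype(float), np.atleast_2d(cov2).astype(float)

    def _floor(c):
        w, v = np.linalg.eigh((c + c.T) / 2)
        if w.min() < eps:
            logger.debug("flooring covariance eigenvalues at %g", eps)
            w = np.maximum(w, eps)
        return (v * w) @ v.T

    cov1, cov2 = _floor(cov1), _floor(cov2)
    diff = mu1 - mu2
    # tr sqrt(C1 C2) via the symmetric form sqrt(C1) C2 sqrt(C1) (same trace);
    # averaging both orderings makes the result exactly swap-invariant even
    # under sqrtm round-off on near-singular (floored) covariances
    def _tr_sqrt(a, b):
        s = scipy.linalg.sqrtm(a)
        if np.iscomplexobj(s):
            s = s.real
        inner = s @ b @ s
        w = np.linalg.eigvalsh((inner + inner.T) / 2)
        return np.sqrt(np.clip(w, 0.0, None)).sum()

    tr_covmean = (_tr_sqrt(cov1, cov2) + _tr_sqrt(cov2, cov1)) / 2.0
    d2 = diff @ diff + np.trace(cov1) + np.trace(cov2) - 2.0 * tr_covmean
    return float(max(d2, 0.0))


def frechet_from_features(x: np.ndarray, y: np.ndarray) -> float:
    """Fréchet distance between Gaussians fitted to two feature matrices,
    after symmetric (pooled) standardization of each feature."""
    x, y = np.atleast_2d(np.asarray(x, float)), np.atleast_2d(np.asarray(y, float))
    # pooled moments assembled commutatively so the result is exactly
    # invariant under swapping the two sets
    n = len(x) + len(y)
    center = (x.sum(axis=0) + y.sum(axis=0)) / n
    second = ((x * x).sum(axis=0) + (y * y).sum(axis=0)) / n
    scale = np.sqrt(np.maximum(second - center * center, 0.0))
    scale[scale == 0] = 1.0
    xs, ys = (x - center) / scale, (y - center) / scale
    return frechet_gaussian(xs.mean(axis=0), np.cov(xs, rowvar=False),
                            ys.mean(axis=0), np.cov(ys, rowvar=False))


def frechet_dist(gen: list[str], ref: list[str],
                 featurizer: str = "descriptor") -> float:
    """Fréchet distance between generated and reference molecule sets."""
    if featurizer == "descriptor":
        feats = descriptor_features
    elif featurizer in _FEATURIZERS:
        feats = _FEATURIZERS[featurizer]
    else:
        raise ValueError(f"unknown featurizer {featurizer!r}")
    x, y = feats(gen), feats(ref)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("frechet_dist needs >= 2 valid molecules per set")
    return frechet_from_features(x, y)


# --------------------------------------------------------------- properties
def property_profile(gen: list[str]) -> pd.DataFrame:
    """Per-molecule QED, LogP (Crippen), SA (Ertl-Schuffenhauer) and MW."""
    rows = []
    for m in _mols(gen):
        rows.append({
            "smiles": Chem.MolToSmiles(m),
            "QED": QED.qed(m),
            "LogP": Crippen.MolLogP(m),
            "SA": sascorer.calculateScore(m),
            "MW": Descriptors.MolWt(m),
        })
    return pd.DataFrame(rows)


def property_summary(profile: pd.DataFrame) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for col in ("QED", "LogP", "SA", "MW"):
        s = profile[col]
        out[col] = {"mean": float(s.mean()), "median": float(s.median()),
                    "q25": float(s.quantile(0.25)), "q75": float(s.quantile(0.75))}
    return out


# ----------------------------------------------------------------- scaffolds
def murcko_scaffold(smiles: str) -> str:
    """Murcko scaffold SMILES; empty string for acyclic molecules."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def scaffold_census(gen: list[str]) -> tuple[int, pd.DataFrame]:
    """Unique non-empty Murcko scaffold count plus a frequency table."""
    counts = _scaffold_counts(gen)
    table = (pd.DataFrame({"scaffold": list(counts), "count": list(counts.values())})
             .sort_values(["count", "scaffold"], ascending=[False, True])
             .reset_index(drop=True))
    return len(counts), table


# -------------------------------------------------------------------- report
@dataclass
class GenerationReport:
    n_generated: int
    validity: float
    uniqueness: float
    novelty: float | None
    int_div: float | None
    snn: float | None
    frag_sim: float | None
    scaff_sim: float | None
    frechet_dist: float | None
    properties: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate(gen: list[str], ref: list[str] | None = None,
             train: list[str] | None = None) -> GenerationReport:
    """Assemble the full metric report for a generated set.

    Reference-dependent metrics are ``None`` when *ref* (or *train* for
    novelty) is not given or a metric is undefined on the inputs.
    """
    if len(gen) == 0:
        raise ValueError("cannot evaluate an empty generated set")
    val = validity(gen)
    valid = canonical_set(gen)
    uniq = len(set(valid)) / len(valid) if valid else 0.0
    report = GenerationReport(
        n_generated=len(gen), validity=val, uniqueness=uniq,
        novelty=novelty(gen, train) if train is not None and valid else None,
        int_div=int_div(valid) if len(set(valid)) >= 2 else None,
        snn=snn(valid, ref) if ref and valid else None,
        frag_sim=frag_sim(valid, ref) if ref and valid else None,
        scaff_sim=scaff_sim(valid, ref) if ref and valid else None,
        frechet_dist=(frechet_dist(valid, ref)
                      if ref and len(valid) >= 2 and len(ref) >= 2 else None),
    )
    if valid:
        report.properties = property_summary(property_profile(valid))
    return report
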