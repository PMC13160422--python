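"""Frozen-latent discriminability probe and latent export.

After the contrastive stage the encoder is frozen and a linear (logistic
regression) classifier is fitted on the latent mean vectors; its holdout
accuracy is the package's quantitative measure of how well the latent space
separates single- from multi-target profiles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support)
from sklearn.model_selection import train_test_split

from . import chem
from .model import SmilesVAE
from .training import smiles_to_ids

logger = logging.getLogger(__name__)


@dataclass
class ProbeReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: list[list[int]]
    classes: list[str]
    split_fraction: float
    seed: int

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


def probe(latents: np.ndarray, labels, split_fraction: float = 0.2,
          seed: int = 0, C: float = 1.0) -> ProbeReport:
    """Fit a linear probe on frozen latents; report holdout metrics.

    Stratified single train/eval split (default 80/20); L2-regularized
    logistic regression; macro-averaged precision/recall/F1. Deterministic
    for a fixed seed.
    """
    latents = np.asarray(latents)
    labels = np.asarray(labels)
    if latents.shape[0] < 10:
        raise ValueError("probe needs at least 10 samples")
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("probe needs at least 2 classes")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must be in (0, 1)")
    X_tr, X_ev, y_tr, y_ev = train_test_split(
        latents, labels, test_size=split_fraction, random_state=seed,
        stratify=labels)
    clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_ev)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_ev, pred, average="macro", zero_division=0)
    cm = confusion_matrix(y_ev, pred, labels=classes)
    return ProbeReport(
        accuracy=float(accuracy_score(y_ev, pred)),
        precision=float(prec), recall=float(rec), f1=float(f1),
        confusion=cm.tolist(), classes=[str(c) for c in classes],
        split_fraction=split_fraction, seed=seed)


def latent_means(model: SmilesVAE, smiles: list[str],
                 batch_size: int = 200) -> np.ndarray:
    """Encode SMILES to latent mean vectors (no sampling, no gradient)."""
    ids = smiles_to_ids(smiles, model.vocab)
    chunks = []
    for start in range(0, len(smiles), batch_size):
        mu, _ = model.encode(ids[start:start + batch_size])
        chunks.append(mu.data.copy())
    return np.concatenate(chunks, axis=0)


def export_latents(model: SmilesVAE, molecules, path: str | Path) -> pd.DataFrame:
    """Write a CSV of canonical SMILES, label and latent means.

    *molecules* may be :class:`~mtmolgen.chem.MoleculeRecord` objects or raw
    SMILES strings; invalid entries are skipped with a logged warning.
    Columns: ``smiles, label, mu_1 .. mu_{d_z}``.
    """
    rows: list[tuple[str, str]] = []
    for m in molecules:
        rec = (m if isinstance(m, chem.MoleculeRecord)
               else chem.MoleculeRecord.from_smiles(m))
        if not rec.valid:
            logger.warning("skipping invalid molecule %r", rec.smiles_raw)
            continue
        rows.append((rec.smiles_canonical, rec.label))
    mus = latent_means(model, [s for s, _ in rows]) if rows else \
        np.zeros((0, model.cfg.latent_dim))
    df = pd.DataFrame(mus, columns=[f"mu_{i+1}" for i in range(mus.shape[1])])
    df.insert(0, "label", [l for _, l in rows])
    df.insert(0, "smiles", [s for s, _ in rows])
    df.to_csv(path, index=False)
    return df
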