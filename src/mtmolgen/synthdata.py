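"""Deterministic fragment-grammar generator of valid, labeled molecules.

Molecules are assembled from ring-containing scaffold templates and small
substituents. Target-class labels are a testing fiction encoded through
three pharmacophore motifs chosen to echo the linkers recurring in kinase
inhibitors:

* motif A — sulfonamide (``S(=O)(=O)N``),
* motif B — morpholine (``N1CCOCC1``),
* motif C — urea (``NC(=O)N``).

A "single-target" molecule carries exactly one motif, a "dual-target"
molecule carries A and B, and a "triplet-target" molecule carries A, B and
C. Presence/absence of every motif is re-verified by RDKit substructure
matching on each emission, so class labels hold by construction. The
combinatorial space (scaffold x slot assignment x substituent choice) is
>10^4, keeping duplicate rates low at corpus scale.

Substituent templates use ring-closure digit 3 so they can never collide
with the scaffold's ring numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import MoleculeRecord

logger = logging.getLogger(__name__)

MOTIF_SMARTS = {
    "A": "S(=O)(=O)N",   # sulfonamide
    "B": "N1CCOCC1",     # morpholine
    "C": "NC(=O)N",      # urea
}

MOTIF_SUBSTITUENTS = {
    "A": ["S(=O)(=O)N", "S(=O)(=O)NC", "S(=O)(=O)N(C)C", "S(=O)(=O)NCC"],
    "B": ["N3CCOCC3", "CN3CCOCC3", "CCN3CCOCC3"],
    "C": ["NC(=O)N", "NC(=O)NC", "NC(=O)N(C)C", "NC(=O)NCC"],
}

#: motif-free substituents (no S(=O)(=O)N, no morpholine ring, no urea);
#: ring closures use digit 3 to stay clear of scaffold numbering
NEUTRAL_SUBSTITUENTS = [
    "C", "CC", "CCC", "CCCC", "CC(C)C", "C(C)(C)C",
    "O", "OC", "OCC", "OCCC", "OC(C)C", "OCC(C)C",
    "F", "Cl", "Br", "I", "C#N", "CC#N", "C=C", "CC=C",
    "N(C)C", "N(CC)CC", "CN(C)C", "CCN(C)C",
    "C(F)(F)F", "OC(F)(F)F", "CO", "CCO", "CCCO", "C(C)O",
    "C(=O)C", "C(=O)OC", "OC(=O)C", "NC(=O)C", "N(C)C(=O)C",
    "C3CC3", "C3CCC3", "C3CCCC3", "C3CCCCC3",
    "c3ccccc3", "c3ccncc3", "Cc3ccccc3", "Oc3ccccc3",
    "N3CCCC3", "N3CCCCC3", "N3CCN(C)CC3",
]

#: scaffold templates grouped by number of substituent slots
SCAFFOLDS = {
    1: ["c1ccc({0})cc1",
        "c1ccc2cc({0})ccc2c1",
        "c1ccc2c(c1)[nH]c({0})c2"],
    2: ["c1cc({0})ccc1{1}",
        "c1nc({0})cc({1})n1",
        "C1CC({0})CCC1{1}",
        "c1cc({0})cnc1{1}"],
    3: ["c1c({0})cc({1})cc1{2}",
        "c1cc(-c2ccc({0})cc2)c({1})cc1{2}"],
}


@dataclass
class GrammarSpec:
    """The assembly grammar: scaffolds, substituents and motif patterns."""

    scaffolds: dict[int, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in SCAFFOLDS.items()})
    neutral: list[str] = field(default_factory=lambda: list(NEUTRAL_SUBSTITUENTS))
    motif_substituents: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in MOTIF_SUBSTITUENTS.items()})
    motif_patterns: dict[str, str] = field(
        default_factory=lambda: dict(MOTIF_SMARTS))
    seed: int = 0

    def compiled_patterns(self) -> dict[str, Chem.Mol]:
        return {k: Chem.MolFromSmarts(v) for k, v in self.motif_patterns.items()}


def motif_flags(smiles: str,
                patterns: dict[str, Chem.Mol] | None = None) -> dict[str, bool]:
    """Which motifs a molecule contains, by substructure match."""
    patterns = patterns or GrammarSpec().compiled_patterns()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return {k: mol.HasSubstructMatch(p) for k, p in patterns.items()}


class MoleculeGenerator:
    """Seeded emitter of valid molecules with controlled motif content."""

    def __init__(self, spec: GrammarSpec | None = None, seed: int = 0):
        self.spec = spec or GrammarSpec(seed=seed)
        self.rng = np.random.default_rng(seed)
        self._patterns = self.spec.compiled_patterns()

    def _pick(self, options: list[str]) -> str:
        return options[self.rng.integers(len(options))]

    def emit(self, motifs: tuple[str, ...] = ()) -> str:
        """Assemble one canonical molecule containing exactly *motifs*.

        The emission is re-verified by substructure match; a molecule whose
        motif content disagrees with the request is discarded and redrawn
        (a hard generator postcondition, not an expected event).
        """
        want = set(motifs)
        for _ in range(100):
            # at least two slots: keeps the combinatorial space large enough
            # for low duplicate rates at corpus scale
            n_slots = int(self.rng.integers(max(len(want), 2), 4))
            tpl = self._pick(self.spec.scaffolds[n_slots])
            slots: list[str] = [self._pick(self.spec.neutral)
                                for _ in range(n_slots)]
            positions = self.rng.permutation(n_slots)[:len(want)]
            for pos, m in zip(positions, sorted(want)):
                slots[pos] = self._pick(self.spec.motif_substituents[m])
            smiles = tpl.format(*slots)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            canonical = Chem.MolToSmiles(mol)
            flags = {k: mol.HasSubstructMatch(p)
                     for k, p in self._patterns.items()}
            if all(flags[k] == (k in want) for k in flags):
                return canonical
        raise RuntimeError(f"grammar failed to emit motifs {motifs}")


def make_pretrain_corpus(n: int, seed: int) -> list[str]:
    """*n* valid, mostly unique drug-like molecules for phase-A pre-training.

    About 40% of emissions carry one random motif so the corpus covers the
    motif chemistry the later stages rely on.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    gen = MoleculeGenerator(seed=seed)
    out = []
    for _ in range(n):
        if gen.rng.random() < 0.4:
            out.append(gen.emit((str(gen.rng.choice(["A", "B", "C"])),)))
        else:
            out.append(gen.emit(()))
    return out


def make_labeled_sets(n_per_class: int, seed: int
                      ) -> dict[str, list[MoleculeRecord]]:
    """Labeled single / dual / triplet benchmark sets.

    Single-class molecules carry exactly one of motifs {A, B, C}; dual carry
    A and B; triplet carry A, B and C.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    gen = MoleculeGenerator(seed=seed)
    sets: dict[str, list[MoleculeRecord]] = {}
    for label, motifs in (("single", None), ("dual", ("A", "B")),
                          ("triplet", ("A", "B", "C"))):
        records = []
        for _ in range(n_per_class):
            m = motifs or (str(gen.rng.choice(["A", "B", "C"])),)
            records.append(MoleculeRecord.from_smiles(gen.emit(m), label=label))
        sets[label] = records
    return sets


def make_seed_sets(seed: int = 0) -> tuple[list[str], list[str]]:
    """The curriculum seed sets: exactly 5 unique dual-motif and 16 unique
    triplet-motif molecules (canonical SMILES)."""
    gen = MoleculeGenerator(seed=seed)
    dual: list[str] = []
    seen: set[str] = set()
    while len(dual) < 5:
        s = gen.emit(("A", "B"))
        if s not in seen:
            seen.add(s)
            dual.append(s)
    triplet: list[str] = []
    while len(triplet) < 16:
        s = gen.emit(("A", "B", "C"))
        if s not in seen:
            seen.add(s)
            triplet.append(s)
    return dual, triplet
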