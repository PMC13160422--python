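"""SMILES handling: canonicalization, tokenization and the fixed-size one-hot codec.

Every molecule that enters the pipeline passes through this module: raw
SMILES are canonicalized with RDKit, split into chemically meaningful tokens
(two-character halogens and bracket atoms are single tokens) and laid out as
a fixed ``(100, 48)`` one-hot matrix — 100 sequence positions over a
48-symbol vocabulary — with explicit ``<bos>``/``<eos>`` delimiters and
``<pad>`` fill.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

MAX_LEN = 100
VOCAB_SIZE = 48
#: maximum payload tokens between <bos> and <eos>
MAX_PAYLOAD = MAX_LEN - 2

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"

_TOKEN_RE = re.compile(r"(\[[^\]]*\]|Cl|Br|%\d\d|.)")


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass(frozen=True)
class Vocabulary:
    """Ordered 48-symbol token inventory with the four special tokens."""

    symbols: tuple[str, ...]
    index_of: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if len(self.symbols) != VOCAB_SIZE:
            raise ValueError(f"vocabulary must have exactly {VOCAB_SIZE} symbols, "
                             f"got {len(self.symbols)}")
        if len(set(self.symbols)) != VOCAB_SIZE:
            raise ValueError("vocabulary symbols must be distinct")
        for tok in (PAD, BOS, EOS, UNK):
            if tok not in self.symbols:
                raise ValueError(f"special token {tok} missing from vocabulary")
        object.__setattr__(self, "index_of",
                           {s: i for i, s in enumerate(self.symbols)})

    @classmethod
    def default(cls) -> "Vocabulary":
        """Load the packaged 48-symbol vocabulary."""
        text = resources.files("mtmolgen.data").joinpath("vocabulary.txt").read_text()
        # comment lines start with "# "; a bare "#" is the triple-bond token
        symbols = [ln for ln in (l.strip() for l in text.splitlines())
                   if ln and not ln.startswith("# ")]
        return cls(tuple(symbols))

    @property
    def pad_id(self) -> int:
        return self.index_of[PAD]

    @property
    def bos_id(self) -> int:
        return self.index_of[BOS]

    @property
    def eos_id(self) -> int:
        return self.index_of[EOS]

    @property
    def unk_id(self) -> int:
        return self.index_of[UNK]

    def ids(self, tokens: Sequence[str]) -> list[int]:
        unk = self.unk_id
        return [self.index_of.get(t, unk) for t in tokens]

    def content_hash(self) -> str:
        """Stable hash of the symbol list, stored in checkpoints."""
        return hashlib.sha256("\n".join(self.symbols).encode()).hexdigest()[:16]

    def __len__(self) -> int:
        return VOCAB_SIZE


@dataclass
class MoleculeRecord:
    """One molecule as read from disk: raw text plus derived chemistry."""

    smiles_raw: str
    smiles_canonical: str | None = None
    valid: bool = False
    label: str = "unlabeled"
    properties: dict[str, float] | None = None

    @classmethod
    def from_smiles(cls, smiles: str, label: str = "unlabeled") -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return cls(smiles_raw=smiles, valid=False, label=label)
        return cls(smiles_raw=smiles, smiles_canonical=Chem.MolToSmiles(mol),
                   valid=True, label=label)


@dataclass
class EncodedSequence:
    """A SMILES laid out as a ``(100, 48)`` one-hot matrix.

    ``true_length`` counts real tokens including ``<bos>`` and ``<eos>``;
    rows at and beyond it hold the ``<pad>`` one-hot.
    """

    matrix: np.ndarray
    true_length: int

    def token_ids(self) -> np.ndarray:
        return self.matrix.argmax(axis=1)


def canonicalize(smiles: str) -> str:
    """Return RDKit's canonical form of *smiles*; idempotent by construction."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return Chem.MolToSmiles(mol)


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens.

    Two-character halogens (Cl, Br), bracket atoms (``[nH]``, ``[O-]``, ...)
    and ``%NN`` ring closures are kept as single tokens; everything else is a
    single character. Concatenating the tokens reproduces the input.
    """
    return _TOKEN_RE.findall(smiles)


def encode(tokens: Sequence[str], vocab: Vocabulary) -> EncodedSequence:
    """Lay out ``<bos> + tokens + <eos>`` over 100 one-hot rows.

    Payloads longer than 98 tokens are truncated so that ``<eos>`` is always
    present (the decode target stays terminable); remaining rows are pad.
    """
    if len(tokens) == 0:
        raise ValueError("cannot encode an empty token list")
    payload = list(tokens)[:MAX_PAYLOAD]
    ids = [vocab.bos_id] + vocab.ids(payload) + [vocab.eos_id]
    n_unk = sum(1 for i in ids if i == vocab.unk_id)
    if n_unk:
        logger.warning("%d token(s) mapped to %s while encoding %r",
                       n_unk, UNK, "".join(tokens))
    matrix = np.zeros((MAX_LEN, VOCAB_SIZE), dtype=np.float32)
    matrix[np.arange(len(ids)), ids] = 1.0
    matrix[len(ids):, vocab.pad_id] = 1.0
    return EncodedSequence(matrix=matrix, true_length=len(ids))


def decode(seq: EncodedSequence, vocab: Vocabulary) -> str:
    """Invert :func:`encode`: read tokens until the first ``<eos>``."""
    ids = seq.token_ids()
    out: list[str] = []
    for i in ids[1:]:  # skip <bos>
        if i == vocab.eos_id or i == vocab.pad_id:
            break
        out.append(vocab.symbols[i])
    if not out:
        logger.warning("decoded an empty payload")
    return "".join(out)


def ids_to_smiles(ids: Iterable[int], vocab: Vocabulary) -> str:
    """Join sampled token ids into a SMILES string, stopping at eos/pad."""
    out = []
    for i in ids:
        if i in (vocab.eos_id, vocab.pad_id):
            break
        if i == vocab.bos_id:
            continue
        out.append(vocab.symbols[i])
    return "".join(out)


def read_smiles_file(path: str | Path, format: str = "plain") -> list[MoleculeRecord]:
    """Read molecules from a plain one-per-line file or a CSV with a
    ``smiles`` column (optional ``label`` column)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    if format == "plain":
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            records.append(MoleculeRecord.from_smiles(line))
    elif format == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise ValueError(f"{path}: CSV must have a 'smiles' column")
            for row in reader:
                records.append(MoleculeRecord.from_smiles(
                    row["smiles"], label=row.get("label") or "unlabeled"))
    else:
        raise ValueError(f"unknown format {format!r}")
    n_valid = sum(r.valid for r in records)
    if not records:
        logger.warning("%s: no molecules read", path)
    logger.info("%s: %d molecules, %d valid, %d invalid",
                path, len(records), n_valid, len(records) - n_valid)
    return records


def write_smiles_file(records: Iterable[MoleculeRecord | str], path: str | Path,
                      format: str = "plain") -> None:
    """Write molecules to disk in the formats of :func:`read_smiles_file`."""
    path = Path(path)
    rows = []
    for r in records:
        if isinstance(r, str):
            rows.append((r, "unlabeled"))
        else:
            rows.append((r.smiles_canonical if r.valid else r.smiles_raw, r.label))
    if format == "plain":
        path.write_text("".join(f"{s}\n" for s, _ in rows))
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["smiles", "label"])
            writer.writerows(rows)
    else:
        raise ValueError(f"unknown format {format!r}")
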