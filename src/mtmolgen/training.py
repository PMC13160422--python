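"""Three-phase training pipeline.

Phase A pre-trains the VAE unsupervised (reconstruction + KL with linear
warm-up of the KL weight). Phase B shapes the latent space with a hybrid
loss adding a supervised contrastive term on projected latent means, so that
single-target and multi-target profiles separate. Phase C is the curriculum:
fine-tune on the 5 dual-target seed molecules, then continue on the 16
triplet-target seeds, with the tiny seed sets amplified by randomized
(non-canonical) SMILES enumeration.

All randomness flows from the ``seed`` in :class:`TrainConfig`; a rerun with
the same config and data reproduces the loss series bit-for-bit.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem

from . import chem
from .autodiff import Tensor
from .model import ConfigError, SmilesVAE
from .nn import Adam, Linear, Module

logger = logging.getLogger(__name__)

STAGES = ("pretrain", "contrastive", "finetune_dual", "finetune_triplet")


@dataclass
class TrainConfig:
    stage: str = "pretrain"
    epochs: int = 10
    batch_size: int = 100
    learning_rate: float = 1e-3
    kl_weight_start: float = 0.0
    kl_weight_end: float = 0.05
    kl_warmup_epochs: int = 10
    contrastive_weight: float = 1.0       # lambda
    contrastive_temperature: float = 0.1  # tau
    augmentation_factor: int = 50         # a: copies per curriculum seed
    seed: int = 0

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}")
        if self.contrastive_temperature <= 0:
            raise ConfigError("contrastive_temperature must be > 0")
        if self.contrastive_weight < 0:
            raise ConfigError("contrastive_weight must be >= 0")
        for b in (self.kl_weight_start, self.kl_weight_end):
            if not 0.0 <= b <= 1.0:
                raise ConfigError("kl weights must lie in [0, 1]")
        if self.augmentation_factor < 1:
            raise ConfigError("augmentation_factor must be >= 1")

    def kl_weight(self, epoch: int) -> float:
        """Linear warm-up of the KL weight over ``kl_warmup_epochs``."""
        if self.kl_warmup_epochs <= 0 or epoch >= self.kl_warmup_epochs:
            return self.kl_weight_end
        frac = epoch / self.kl_warmup_epochs
        return self.kl_weight_start + frac * (self.kl_weight_end - self.kl_weight_start)


@dataclass
class StageReport:
    stage: str
    losses: dict[str, list[float]] = field(default_factory=dict)
    checkpoint_path: str | None = None
    epochs_run: int = 0
    wall_seconds: float = 0.0

    def as_dict(self) -> dict:
        return asdict(self)


class ProjectionHead(Module):
    """2-layer MLP mapping latent means to L2-normalized contrastive space."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.fc1 = Linear(d_in, d_in, rng)
        self.fc2 = Linear(d_in, d_out, rng)

    def __call__(self, mu: Tensor) -> Tensor:
        h = self.fc2(self.fc1(mu).tanh())
        norm = (h * h).sum(axis=-1, keepdims=True).pow(0.5)
        return h / (norm + 1e-12)


# ---------------------------------------------------------------------- losses
def loss_reconstruction(logits: Tensor, targets: np.ndarray, pad_id: int) -> Tensor:
    """Mean cross-entropy (nats) per non-pad token position."""
    from .autodiff import cross_entropy_mean
    mask = (targets != pad_id).astype(np.float32)
    return cross_entropy_mean(logits, targets, mask)


def loss_supcon(projections: Tensor, labels: np.ndarray, tau: float) -> Tensor:
    """Supervised contrastive loss over L2-normalized projections.

    Mean over anchors that have at least one same-label positive of
    ``-(1/|P(i)|) * sum_p log[ exp(s_ip/tau) / sum_{a != i} exp(s_ia/tau) ]``
    with dot-product similarity. Batches without any positive pair return 0
    with a warning.
    """
    B = projections.shape[0]
    if B < 2:
        raise ValueError("supervised contrastive loss needs a batch of >= 2")
    norms = np.sqrt((projections.data ** 2).sum(axis=-1))
    if not np.allclose(norms, 1.0, atol=1e-3):
        raise ValueError("projections must be L2-normalized")
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    eye = np.eye(B, dtype=bool)
    pos_mask = (same & ~eye).astype(np.float32)
    n_pos = pos_mask.sum(axis=1)
    if n_pos.sum() == 0:
        logger.warning("supcon: batch has no positive pairs; returning 0")
        return Tensor(0.0)

    sim = (projections @ projections.swapaxes(-1, -2)) * (1.0 / tau)
    neg_inf = np.where(eye, -1e9, 0.0).astype(np.float32)
    shifted = sim + Tensor(neg_inf)
    m = shifted.data.max(axis=-1, keepdims=True)
    lse = ((shifted - Tensor(m)).exp().sum(axis=-1, keepdims=True)).log() + Tensor(m)
    log_prob = sim - lse                              # (B, B)
    anchor = (n_pos > 0)
    per_anchor = (log_prob * Tensor(pos_mask)).sum(axis=1) / Tensor(
        np.maximum(n_pos, 1.0))
    sel = anchor.astype(np.float32)
    return -(per_anchor * Tensor(sel)).sum() / float(sel.sum())


# ------------------------------------------------------------------ utilities
def smiles_to_ids(smiles_list: list[str], vocab: chem.Vocabulary) -> np.ndarray:
    """Tokenize and pad a SMILES list to an ``(N, max_len)`` id matrix."""
    out = np.full((len(smiles_list), chem.MAX_LEN), vocab.pad_id, dtype=np.int64)
    for i, s in enumerate(smiles_list):
        toks = chem.tokenize(s)[:chem.MAX_PAYLOAD]
        ids = [vocab.bos_id] + vocab.ids(toks) + [vocab.eos_id]
        out[i, :len(ids)] = ids
    return out


def augment_seeds(seeds: list[str], factor: int, seed: int) -> list[str]:
    """Amplify curriculum seeds with randomized SMILES enumeration.

    Each seed contributes its canonical form plus ``factor - 1`` randomized
    (non-canonical) renderings, so ``factor`` strings per seed in total.
    """
    out: list[str] = []
    for i, s in enumerate(seeds):
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise chem.InvalidSmilesError(s)
        out.append(Chem.MolToSmiles(mol))
        if factor > 1:
            out.extend(Chem.MolToRandomSmilesVect(mol, factor - 1,
                                                  randomSeed=seed + i))
    return out


def _check_finite(value: float, what: str) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"{what} became non-finite; aborting "
                           "(reduce learning rate or batch size)")


# -------------------------------------------------------------------- stages
def _train_loop(model: SmilesVAE, ids: np.ndarray, cfg: TrainConfig,
                labels: np.ndarray | None = None,
                head: ProjectionHead | None = None) -> StageReport:
    """Shared epoch loop for all stages; contrastive term active when
    *labels* and *head* are given and ``contrastive_weight > 0``."""
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)
    params = dict(model.parameters())
    if head is not None:
        params.update({f"proj.{k}": v for k, v in head.parameters().items()})
    opt = Adam(params, lr=cfg.learning_rate)
    pad = model.vocab.pad_id
    use_con = labels is not None and head is not None and cfg.contrastive_weight > 0

    series: dict[str, list[float]] = {
        "reconstruction": [], "kl": [], "contrastive": [], "total": []}
    n = ids.shape[0]
    for epoch in range(cfg.epochs):
        beta = cfg.kl_weight(epoch)
        order = rng.permutation(n)
        ep = {k: 0.0 for k in series}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            take = order[start:start + cfg.batch_size]
            if len(take) < 2:
                continue
            batch = ids[take]
            mu, logvar = model.encode(batch)
            z = model.reparameterize(mu, logvar, rng)
            logits = model.decode_logits(z, batch)
            rec = loss_reconstruction(logits, batch, pad)
            kl = model.kl_divergence(mu, logvar)
            total = rec + beta * kl
            con_val = 0.0
            if use_con:
                con = loss_supcon(head(mu), labels[take],
                                  cfg.contrastive_temperature)
                total = total + cfg.contrastive_weight * con
                con_val = float(con.data)
            opt.zero_grad()
            total.backward()
            opt.step()
            _check_finite(float(total.data), "training loss")
            ep["reconstruction"] += float(rec.data)
            ep["kl"] += float(kl.data)
            ep["contrastive"] += con_val
            ep["total"] += float(total.data)
            n_batches += 1
        for k in series:
            series[k].append(ep[k] / max(n_batches, 1))
        logger.info("%s epoch %d: total %.4f rec %.4f kl %.4f con %.4f",
                    cfg.stage, epoch, series["total"][-1],
                    series["reconstruction"][-1], series["kl"][-1],
                    series["contrastive"][-1])
    return StageReport(stage=cfg.stage, losses=series, epochs_run=cfg.epochs,
                       wall_seconds=time.time() - t0)


def run_pretrain(corpus: list[str], model: SmilesVAE, cfg: TrainConfig,
                 checkpoint_out: str | Path | None = None) -> StageReport:
    """Phase A: unsupervised pre-training on a SMILES corpus."""
    if len(corpus) == 0:
        raise ValueError("empty pre-training corpus")
    ids = smiles_to_ids(corpus, model.vocab)
    report = _train_loop(model, ids, cfg)
    if checkpoint_out is not None:
        model.save(checkpoint_out, meta={"stage": cfg.stage})
        report.checkpoint_path = str(checkpoint_out)
    return report


def run_contrastive(smiles: list[str], labels: list[str], model: SmilesVAE,
                    cfg: TrainConfig, proj_dim: int = 32,
                    checkpoint_out: str | Path | None = None
                    ) -> tuple[StageReport, ProjectionHead]:
    """Phase B: hybrid reconstruction + KL + supervised contrastive loss."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("contrastive stage needs at least 2 classes")
    ids = smiles_to_ids(list(smiles), model.vocab)
    head = ProjectionHead(model.cfg.latent_dim, proj_dim,
                          np.random.default_rng(cfg.seed + 1))
    report = _train_loop(model, ids, cfg, labels=labels, head=head)
    if checkpoint_out is not None:
        model.save(checkpoint_out, meta={"stage": cfg.stage})
        report.checkpoint_path = str(checkpoint_out)
    return report, head


def run_finetune(seeds: list[str], model: SmilesVAE, cfg: TrainConfig,
                 checkpoint_out: str | Path | None = None) -> StageReport:
    """One curriculum sub-stage on a tiny seed set, amplified by enumeration."""
    canon = []
    seen = set()
    for s in seeds:
        c = chem.canonicalize(s)
        if c in seen:
            logger.warning("duplicate curriculum seed collapsed: %s", c)
            continue
        seen.add(c)
        canon.append(c)
    if not canon:
        raise ValueError("empty curriculum seed set")
    train = augment_seeds(canon, cfg.augmentation_factor, cfg.seed)
    ids = smiles_to_ids(train, model.vocab)
    report = _train_loop(model, ids, cfg)
    if checkpoint_out is not None:
        model.save(checkpoint_out, meta={"stage": cfg.stage})
        report.checkpoint_path = str(checkpoint_out)
    return report


def run_curriculum(seeds_dual: list[str], seeds_triplet: list[str],
                   model: SmilesVAE, cfg_dual: TrainConfig,
                   cfg_triplet: TrainConfig,
                   checkpoint_dir: str | Path | None = None
                   ) -> tuple[StageReport, StageReport]:
    """Phase C: dual-target fine-tuning, then triplet-target fine-tuning.

    The curriculum order is enforced: stage II always continues from the
    stage-I weights produced here.
    """
    if cfg_dual.stage != "finetune_dual" or cfg_triplet.stage != "finetune_triplet":
        raise ConfigError("curriculum configs must be finetune_dual then "
                          "finetune_triplet")
    ckpt_dual = ckpt_trip = None
    if checkpoint_dir is not None:
        d = Path(checkpoint_dir)
        d.mkdir(parents=True, exist_ok=True)
        ckpt_dual, ckpt_trip = d / "finetune_dual.npz", d / "finetune_triplet.npz"
    rep_dual = run_finetune(seeds_dual, model, cfg_dual, ckpt_dual)
    rep_trip = run_finetune(seeds_triplet, model, cfg_triplet, ckpt_trip)
    return rep_dual, rep_trip
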