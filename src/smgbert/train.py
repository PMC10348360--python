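"""Pre-training and fine-tuning.

Pre-training runs the full pipeline per step: corrupt token sequences →
encode with the modified attention → evaluate the four SSL losses →
uncertainty-weighted total → Adam step (σ parameters updated by the same
optimizer as the network weights).  Fine-tuning puts a two-layer ReLU head on
the global-node representation ``r[0]`` and optimizes the task loss plus the
pre-training loss retained as a regularization term.

Datasets are split 80/10/10 by Bemis–Murcko scaffold by default, so
structurally related molecules never span two splits.

Ablation switches give the channel-removal variants:

* ``no_3d``   — the distance fraction matrix D is zeroed and the 3D
  reconstruction loss is dropped (no 3D information reaches the model through
  inputs or supervision);
* ``no_chem`` — NMR tokens are replaced by a constant token, Bnorm by the
  plain adjacency M, and the NMR/bond-energy losses are dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn import metrics as skmetrics

from .autodiff import Tensor, no_grad
from .chemfeat import (AtomVocab, FeaturizeConfig, GeometryTargets, NmrVocab,
                       PairChannels, TokenPair, build_channels, build_token_pair,
                       geometry_targets)
from .corruption import DEFAULT_SELECT_RATE, DEFAULT_SPLIT, corrupt_pair
from .encoder import (Batch, EncoderConfig, SMGBertEncoder, collate,
                      load_checkpoint, save_checkpoint)
from .molio import (GeometryError, Molecule, ParseError, PropertyTable,
                    embed_conformer, parse_smiles)
from .nn import MLP, Adam, Module
from .ssl import PretrainHeads, compute_pretrain_loss

logger = logging.getLogger("smgbert")

__all__ = [
    "MoleculeData",
    "featurize",
    "SplitSpec",
    "scaffold_split",
    "PretrainConfig",
    "PretrainModel",
    "pretrain",
    "masked_atom_accuracy",
    "FinetuneConfig",
    "FinetuneModel",
    "finetune",
    "finetune_runs",
    "predict",
    "ablation_study",
    "rmse",
    "r2",
    "roc_auc",
    "default_config",
    "config_from_dict",
]


# ------------------------------------------------------------------ featurize

@dataclass
class MoleculeData:
    """Everything the model needs for one molecule."""

    molecule: Molecule
    tokens: TokenPair
    channels: PairChannels
    geometry: GeometryTargets
    label: Optional[float] = None

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    def bonded_pairs(self) -> np.ndarray:
        return np.array([(i, j) for i, j, _ in self.molecule.bonds],
                        dtype=np.intp).reshape(-1, 2)

    def bond_targets(self) -> np.ndarray:
        return np.array([self.channels.Bnorm[i + 1, j + 1]
                         for i, j, _ in self.molecule.bonds])


def _conformer_seed(master_seed: int, smiles: str) -> int:
    import zlib
    return (int(master_seed) * 1_000_003 + zlib.crc32(smiles.encode())) % (2 ** 31 - 1)


def featurize(smiles: Sequence[str], feat_cfg: FeaturizeConfig,
              atom_vocab: AtomVocab, nmr_vocab: NmrVocab,
              seed: int = 0,
              labels: Optional[Sequence[float]] = None,
              molecules: Optional[Sequence[Molecule]] = None,
              no_chem: bool = False) -> List[MoleculeData]:
    """Parse, embed conformers (seeded per molecule) and build all channels.

    Molecules that fail to parse or embed are skipped with a warning.  With
    ``no_chem``, NMR tokens collapse to one constant token and Bnorm is
    replaced by the adjacency matrix M.
    """
    out: List[MoleculeData] = []
    n_failed = 0
    for idx, s in enumerate(smiles):
        try:
            m = molecules[idx] if molecules is not None else parse_smiles(s)
            if m.coords is None:
                m = embed_conformer(m, _conformer_seed(seed, m.smiles))
            tp = build_token_pair(m, feat_cfg, atom_vocab, nmr_vocab)
            ch = build_channels(m)
            if no_chem:
                const = nmr_vocab.bin_id(0)
                tp.nmr_tokens[1:] = const
                ch.Bnorm = ch.M.copy()
            geo = geometry_targets(m, signed_torsions=feat_cfg.signed_torsions)
            out.append(MoleculeData(molecule=m, tokens=tp, channels=ch, geometry=geo,
                                    label=None if labels is None else float(labels[idx])))
        except (ParseError, GeometryError) as exc:
            n_failed += 1
            logger.warning("skipping %r: %s", s, exc)
    if n_failed:
        logger.warning("featurization skipped %d molecule(s)", n_failed)
    return out


# -------------------------------------------------------------------- metrics

def rmse(y_true, y_pred) -> float:
    return float(np.sqrt(skmetrics.mean_squared_error(y_true, y_pred)))


def r2(y_true, y_pred) -> float:
    return float(skmetrics.r2_score(y_true, y_pred))


def roc_auc(y_true, y_score) -> float:
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC-AUC undefined: split contains a single class")
    return float(skmetrics.roc_auc_score(y_true, y_score))


# ---------------------------------------------------------------------- split

@dataclass(frozen=True)
class SplitSpec:
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    method: str = "scaffold"     # scaffold | random
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.method not in ("scaffold", "random"):
            raise ValueError(f"unknown split method {self.method!r}")


def _random_split(n: int, spec: SplitSpec) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    order = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(round(spec.fractions[0] * n))
    n_valid = int(round(spec.fractions[1] * n))
    return order[:n_train], order[n_train:n_train + n_valid], order[n_train + n_valid:]


def scaffold_split(table: PropertyTable, spec: SplitSpec = SplitSpec()
                   ) -> Tuple[List[int], List[int], List[int]]:
    """80/10/10 split at the Bemis–Murcko scaffold level.

    Scaffold groups (sorted by size descending, ties by scaffold string) are
    greedily assigned to fill train, then validation, then test, so no scaffold
    ever spans two splits.  Fewer than three distinct scaffolds triggers a
    random fallback with a warning.
    """
    n = len(table)
    if spec.method == "random":
        tr, va, te = _random_split(n, spec)
        return list(tr), list(va), list(te)
    groups: Dict[str, List[int]] = {}
    for idx, s in enumerate(table.smiles):
        scaf = MurckoScaffold.MurckoScaffoldSmiles(mol=Chem.MolFromSmiles(s))
        groups.setdefault(scaf, []).append(idx)
    if len(groups) < 3:
        logger.warning("only %d distinct scaffold(s); falling back to a random split",
                       len(groups))
        tr, va, te = _random_split(n, spec)
        return list(tr), list(va), list(te)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n_train = int(round(spec.fractions[0] * n))
    n_valid = int(round(spec.fractions[1] * n))
    train, valid, test = [], [], []
    for _, idxs in ordered:
        if len(train) < n_train:
            train.extend(idxs)
        elif len(valid) < n_valid:
            valid.extend(idxs)
        else:
            test.extend(idxs)
    return train, valid, test


# ----------------------------------------------------------------- pretraining

@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 100
    batch_size: int = 4
    lr: float = 2e-3
    warmup_steps: int = 100
    sigma_lr: Optional[float] = None  # lr for the 4 log-sigma scalars; None -> 25*lr
    grad_clip: float = 0.0          # 0 disables clipping
    select_rate: float = DEFAULT_SELECT_RATE
    split: Tuple[float, float, float] = DEFAULT_SPLIT
    include_keep: bool = True       # count "keep" positions in L_A/L_N
    mean_losses: bool = True        # family means rather than raw sums
    seed: int = 0
    no_3d: bool = False
    no_chem: bool = False
    log_path: Optional[str] = None  # JSONL loss records
    checkpoint_path: Optional[str] = None


class PretrainModel(Module):
    """Encoder plus SSL heads — the unit that is checkpointed."""

    def __init__(self, enc_cfg: EncoderConfig, feat_cfg: FeaturizeConfig = FeaturizeConfig()):
        super().__init__()
        self.enc_cfg = enc_cfg
        self.feat_cfg = feat_cfg
        self.atom_vocab = AtomVocab()
        self.nmr_vocab = NmrVocab(feat_cfg.nmr_bin_width, feat_cfg.nmr_range)
        self.encoder = SMGBertEncoder(enc_cfg, self.atom_vocab, self.nmr_vocab)
        rng = np.random.default_rng(enc_cfg.seed + 1)
        self.heads = PretrainHeads(enc_cfg.d_model, len(self.atom_vocab),
                                   len(self.nmr_vocab), rng)


def _ssl_batch_inputs(mols: Sequence[MoleculeData], model: PretrainModel,
                      cfg: PretrainConfig, corrupt_seeds: Sequence[int]):
    """Corrupt each molecule and assemble the padded batch + loss bookkeeping."""
    items, atom_plans, nmr_plans, bonds, bond_targets, geo = [], [], [], [], [], []
    for b, (md, cs) in enumerate(zip(mols, corrupt_seeds)):
        a_c, a_plan, n_c, n_plan = corrupt_pair(md.tokens, cfg.select_rate,
                                                cfg.split, seed=int(cs))
        items.append((a_c, n_c, md.channels))
        atom_plans.append((b, a_plan))
        nmr_plans.append((b, n_plan))
        bonds.append((b, md.bonded_pairs()))
        bond_targets.append(md.bond_targets())
        geo.append((b, md.molecule.n_atoms, md.geometry))
    batch = collate(items, model.atom_vocab.pad, model.nmr_vocab.pad)
    return batch, atom_plans, nmr_plans, bonds, bond_targets, geo


def _pretrain_step_loss(model: PretrainModel, cfg: PretrainConfig,
                        batch, atom_plans, nmr_plans, bonds, bond_targets, geo):
    state = model.encoder(batch, no_3d=cfg.no_3d)
    if cfg.no_3d:
        geo = []
    if cfg.no_chem:
        nmr_plans = []
        bonds, bond_targets = [], []
    # empty plan lists would warn every step; silence by passing through
    loss, bd = compute_pretrain_loss(
        state.r, model.heads,
        atom_plans=atom_plans, nmr_plans=nmr_plans,
        bonds=bonds, bond_targets=bond_targets, geo=geo,
        include_keep=cfg.include_keep, mean_losses=cfg.mean_losses,
        signed_torsions=model.feat_cfg.signed_torsions,
    )
    return loss, bd


@dataclass
class PretrainResult:
    model: PretrainModel
    history: List[Dict[str, float]]   # per-step loss breakdowns
    checkpoint_path: Optional[str]


def pretrain(mol_data: Sequence[MoleculeData], enc_cfg: EncoderConfig,
             cfg: PretrainConfig = PretrainConfig(),
             feat_cfg: FeaturizeConfig = FeaturizeConfig(),
             resume: Optional[str] = None) -> PretrainResult:
    """Full pre-training loop: featurize → corrupt → encode → SSL losses →
    Adam step.  Deterministic for a fixed seed; aborts on divergence keeping
    the last finite state; resumable from a checkpoint."""
    if len(mol_data) < 2:
        raise ValueError("pre-training needs at least 2 molecules")
    model = PretrainModel(enc_cfg, feat_cfg)
    net_params = [p for n, p in model.named_parameters() if not n.endswith("log_sigmas")]
    opt = Adam(net_params, lr=cfg.lr, warmup_steps=cfg.warmup_steps)
    # the 4 task-balance scalars converge to their stationary point quickly
    sigma_lr = cfg.sigma_lr if cfg.sigma_lr is not None else 25.0 * cfg.lr
    opt_sigma = Adam([model.heads.log_sigmas], lr=sigma_lr)
    start_epoch = 0
    if resume is not None:
        header, state = load_checkpoint(resume)
        model.load_state_dict(state)
        start_epoch = int(header.get("epoch", 0))
        logger.info("resumed from %s at epoch %d", resume, start_epoch)
    rng = np.random.default_rng(cfg.seed)
    # burn the shuffle/corruption stream up to the resume point
    history: List[Dict[str, float]] = []
    log_fh = open(cfg.log_path, "a") if cfg.log_path else None
    last_good: Optional[Dict[str, np.ndarray]] = None
    step = 0
    try:
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(mol_data))
            corrupt_seeds = rng.integers(0, 2 ** 31 - 1, size=len(mol_data))
            if epoch < start_epoch:
                continue
            for lo in range(0, len(order), cfg.batch_size):
                sel = order[lo:lo + cfg.batch_size]
                mols = [mol_data[i] for i in sel]
                inputs = _ssl_batch_inputs(mols, model, cfg, corrupt_seeds[lo:lo + cfg.batch_size])
                try:
                    loss, bd = _pretrain_step_loss(model, cfg, *inputs)
                except FloatingPointError:
                    logger.error("divergence at epoch %d step %d; aborting with last "
                                 "good checkpoint", epoch, step)
                    if last_good is not None:
                        model.load_state_dict(last_good)
                    break
                opt.zero_grad()
                opt_sigma.zero_grad()
                loss.backward()
                if cfg.grad_clip:
                    opt.clip_grad_norm(cfg.grad_clip)
                opt.step()
                opt_sigma.step()
                rec = {"step": step, "epoch": epoch, **bd.as_dict()}
                history.append(rec)
                if log_fh:
                    log_fh.write(json.dumps(rec) + "\n")
                step += 1
            last_good = model.state_dict()
    finally:
        if log_fh:
            log_fh.close()
    path = None
    if cfg.checkpoint_path:
        path = str(cfg.checkpoint_path)
        save_checkpoint(path, model, enc_cfg,
                        extra_header={"epoch": cfg.epochs,
                                      "feat_cfg": vars(feat_cfg) | {"nmr_range": list(feat_cfg.nmr_range)},
                                      "kind": "pretrain"})
    return PretrainResult(model=model, history=history, checkpoint_path=path)


def masked_atom_accuracy(model: PretrainModel, mol_data: Sequence[MoleculeData],
                         cfg: PretrainConfig, seed: int = 12345) -> Tuple[float, float]:
    """Held-out masked-atom reconstruction accuracy at ``<M>`` positions and
    the majority-class baseline (frequency of the most common atom token among
    the evaluated positions)."""
    model.eval()
    rng = np.random.default_rng(seed)
    correct = total = 0
    label_counts: Dict[int, int] = {}
    with no_grad():
        for lo in range(0, len(mol_data), 16):
            mols = mol_data[lo:lo + 16]
            seeds = rng.integers(0, 2 ** 31 - 1, size=len(mols))
            batch, atom_plans, _, _, _, _ = _ssl_batch_inputs(mols, model, cfg, seeds)
            state = model.encoder(batch, no_3d=cfg.no_3d)
            for b, plan in atom_plans:
                masked = plan.actions == "mask"
                if not masked.any():
                    continue
                pos, orig = plan.selected[masked], plan.originals[masked]
                logits = model.heads.atom_head(Tensor(state.r.data[b, pos])).data
                pred = logits.argmax(axis=1)
                correct += int((pred == orig).sum())
                total += len(orig)
                for lab in orig:
                    label_counts[int(lab)] = label_counts.get(int(lab), 0) + 1
    model.train()
    majority = max(label_counts.values()) / total if total else 0.0
    return (correct / total if total else 0.0), majority


# ----------------------------------------------------------------- fine-tuning

@dataclass(frozen=True)
class FinetuneConfig:
    task: str = "regression"            # regression | binary
    head_hidden: int = 128
    dropout: float = 0.1
    pretrain_reg_weight: float = 0.1    # weight of the retained SSL loss
    epochs: int = 20
    batch_size: int = 20
    lr: float = 1e-3
    warmup_steps: int = 100
    seed: int = 0
    freeze_encoder: bool = False
    no_3d: bool = False
    no_chem: bool = False

    def __post_init__(self):
        if self.task not in ("regression", "binary"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.pretrain_reg_weight < 0:
            raise ValueError("pretrain_reg_weight must be >= 0")


class FinetuneModel(Module):
    """Pre-trained (or fresh) encoder + two-layer ReLU prediction head on the
    global-node representation."""

    def __init__(self, pretrained: PretrainModel, ft_cfg: FinetuneConfig):
        super().__init__()
        self.base = pretrained
        self.cfg = ft_cfg
        rng = np.random.default_rng(ft_cfg.seed + 7)
        self.head = MLP(pretrained.enc_cfg.d_model, ft_cfg.head_hidden, 1, rng,
                        dropout=ft_cfg.dropout)
        self.y_mean = 0.0
        self.y_std = 1.0

    def forward(self, batch: Batch):
        state = self.base.encoder(batch, no_3d=self.cfg.no_3d)
        g = state.r[:, 0]          # (B, d_model): the <G> representation
        out = self.head(g).reshape(batch.n_mols)
        return out, state

    def predict_values(self, batch: Batch) -> np.ndarray:
        with no_grad():
            out, _ = self.forward(batch)
        raw = out.data
        if self.cfg.task == "binary":
            return 1.0 / (1.0 + np.exp(-raw))
        return raw * self.y_std + self.y_mean


def _task_loss(pred: Tensor, y: np.ndarray, task: str) -> Tensor:
    if task == "regression":
        return ((pred - Tensor(y)) ** 2).mean()
    # binary cross-entropy on logits, numerically stable softplus form
    z, t = pred, Tensor(y)
    return (z.relu() - z * t + (1.0 + (z.relu() * (-2.0) + z).exp()).log()).mean()


@dataclass
class FinetuneResult:
    model: FinetuneModel
    metrics: Dict[str, float]
    splits: Tuple[List[int], List[int], List[int]]
    history: List[Dict[str, float]]


def finetune(pretrained: PretrainModel, table: PropertyTable, property_name: str,
             ft_cfg: FinetuneConfig = FinetuneConfig(),
             split_spec: SplitSpec = SplitSpec(),
             mol_data: Optional[List[MoleculeData]] = None) -> FinetuneResult:
    """Fine-tune on one property column; reports RMSE and R² (regression) or
    ROC-AUC (binary) on the test split.

    Objective per batch: task loss + ``pretrain_reg_weight`` · SSL total (the
    pre-training loss retained as a regularization term).
    """
    if property_name not in table.task_types:
        raise KeyError(f"unknown property {property_name!r}")
    model = FinetuneModel(pretrained, ft_cfg)
    labels = table.labels(property_name)
    if mol_data is None:
        mol_data = featurize(table.smiles, pretrained.feat_cfg,
                             pretrained.atom_vocab, pretrained.nmr_vocab,
                             seed=ft_cfg.seed, labels=labels,
                             no_chem=ft_cfg.no_chem)
    if len(mol_data) != len(table):
        raise ValueError("featurization dropped molecules; clean the table first")
    tr, va, te = scaffold_split(table, split_spec)
    y = labels
    if ft_cfg.task == "regression":
        model.y_mean = float(y[tr].mean())
        model.y_std = float(y[tr].std()) or 1.0
        y_fit = (y - model.y_mean) / model.y_std
    else:
        classes = set(np.unique(y[tr]))
        if len(classes) < 2:
            raise ValueError("training split contains a single class")
        y_fit = y.astype(float)

    params = model.head.parameters() + model.base.heads.parameters()
    if not ft_cfg.freeze_encoder:
        params = params + model.base.encoder.parameters()
    opt = Adam(params, lr=ft_cfg.lr, warmup_steps=ft_cfg.warmup_steps)
    rng = np.random.default_rng(ft_cfg.seed)
    pt_like = PretrainConfig(no_3d=ft_cfg.no_3d, no_chem=ft_cfg.no_chem,
                             seed=ft_cfg.seed)
    history = []
    for epoch in range(ft_cfg.epochs):
        order = rng.permutation(len(tr))
        corrupt_seeds = rng.integers(0, 2 ** 31 - 1, size=len(tr))
        for lo in range(0, len(tr), ft_cfg.batch_size):
            idxs = [tr[i] for i in order[lo:lo + ft_cfg.batch_size]]
            mols = [mol_data[i] for i in idxs]
            inputs = _ssl_batch_inputs(mols, model.base, pt_like,
                                       corrupt_seeds[lo:lo + ft_cfg.batch_size])
            batch = inputs[0]
            pred, state = model.forward(batch)
            loss = _task_loss(pred, y_fit[idxs], ft_cfg.task)
            if ft_cfg.pretrain_reg_weight > 0:
                ssl_loss, _ = compute_pretrain_loss(
                    state.r, model.base.heads,
                    atom_plans=inputs[1], nmr_plans=[] if ft_cfg.no_chem else inputs[2],
                    bonds=[] if ft_cfg.no_chem else inputs[3],
                    bond_targets=[] if ft_cfg.no_chem else inputs[4],
                    geo=[] if ft_cfg.no_3d else inputs[5],
                    include_keep=True, mean_losses=True,
                    signed_torsions=pretrained.feat_cfg.signed_torsions)
                loss = loss + ft_cfg.pretrain_reg_weight * ssl_loss
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append({"epoch": epoch, "loss": float(loss.data)})

    # evaluation on the test split
    model.eval()
    results: Dict[str, float] = {}
    te_mols = [mol_data[i] for i in te]
    preds = _predict_mols(model, te_mols)
    if ft_cfg.task == "regression":
        results["rmse"] = rmse(y[te], preds)
        results["r2"] = r2(y[te], preds)
    else:
        results["roc_auc"] = roc_auc(y[te], preds)
    model.train()
    return FinetuneResult(model=model, metrics=results, splits=(tr, va, te),
                          history=history)


def _predict_mols(model: FinetuneModel, mols: Sequence[MoleculeData],
                  batch_size: int = 32) -> np.ndarray:
    preds = []
    for lo in range(0, len(mols), batch_size):
        chunk = mols[lo:lo + batch_size]
        items = [(md.tokens.atom_tokens, md.tokens.nmr_tokens, md.channels)
                 for md in chunk]
        batch = collate(items, model.base.atom_vocab.pad, model.base.nmr_vocab.pad)
        preds.append(model.predict_values(batch))
    return np.concatenate(preds) if preds else np.zeros(0)


def finetune_runs(pretrained: PretrainModel, table: PropertyTable, property_name: str,
                  ft_cfg: FinetuneConfig, split_spec: SplitSpec,
                  n_runs: int = 5,
                  mol_data: Optional[List[MoleculeData]] = None) -> Dict[str, object]:
    """n independent fine-tuning runs (different seeds); mean ± sd per metric."""
    records = []
    for k in range(n_runs):
        cfg_k = replace(ft_cfg, seed=ft_cfg.seed + 1000 * k)
        res = finetune(pretrained, table, property_name, cfg_k, split_spec,
                       mol_data=mol_data)
        records.append(res.metrics)
    summary = {}
    for key in records[0]:
        vals = np.array([r[key] for r in records])
        summary[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                        "runs": [float(v) for v in vals]}
    return summary


def ablation_study(pre_table: PropertyTable, ft_table: PropertyTable,
                   property_name: str, enc_cfg: EncoderConfig,
                   feat_cfg: FeaturizeConfig = FeaturizeConfig(),
                   pt_cfg: PretrainConfig = PretrainConfig(),
                   ft_cfg: FinetuneConfig = FinetuneConfig(),
                   split_spec: SplitSpec = SplitSpec(),
                   n_seeds: int = 5) -> Dict[str, Dict[str, object]]:
    """Full model vs the no-3D and no-chemistry variants on one task.

    Each variant pre-trains with its own input channels and losses, then
    fine-tunes ``n_seeds`` times; per-variant metric mean ± sd is returned.
    """
    variants = {"full": {}, "no_3d": {"no_3d": True}, "no_chem": {"no_chem": True}}
    out: Dict[str, Dict[str, object]] = {}
    labels = ft_table.labels(property_name)
    for name, flags in variants.items():
        model_cfg = replace(pt_cfg, **flags)
        atom_vocab, nmr_vocab = AtomVocab(), NmrVocab(feat_cfg.nmr_bin_width,
                                                      feat_cfg.nmr_range)
        md_pre = featurize(pre_table.smiles, feat_cfg, atom_vocab, nmr_vocab,
                           seed=pt_cfg.seed, no_chem=flags.get("no_chem", False))
        pre = pretrain(md_pre, enc_cfg, model_cfg, feat_cfg)
        md_ft = featurize(ft_table.smiles, feat_cfg, pre.model.atom_vocab,
                          pre.model.nmr_vocab, seed=ft_cfg.seed, labels=labels,
                          no_chem=flags.get("no_chem", False))
        variant_ft = replace(ft_cfg, **flags)
        out[name] = finetune_runs(pre.model, ft_table, property_name, variant_ft,
                                  split_spec, n_runs=n_seeds, mol_data=md_ft)
    return out


def predict(model: FinetuneModel, smiles: Sequence[str], seed: int = 0
            ) -> List[Dict[str, object]]:
    """Per-molecule predictions; failures are flagged and the batch continues."""
    out: List[Dict[str, object]] = []
    for s in smiles:
        try:
            md = featurize([s], model.base.feat_cfg, model.base.atom_vocab,
                           model.base.nmr_vocab, seed=seed,
                           no_chem=model.cfg.no_chem)
            if not md:
                raise ParseError(f"could not featurize {s!r}")
            val = float(_predict_mols(model, md)[0])
            out.append({"smiles": s, "prediction": val, "error": None})
        except (ParseError, GeometryError, ValueError) as exc:
            out.append({"smiles": s, "prediction": None, "error": str(exc)})
    return out


# ------------------------------------------------------------------- config

def default_config() -> Dict[str, dict]:
    """Every tunable default, grouped by pipeline stage."""
    return {
        "featurize": {
            "use_chiral_tokens": True,
            "signed_torsions": False,
            "nmr_bin_width": 1.0,
            "nmr_range": [-50.0, 300.0],
        },
        "corruption": {
            "select_rate": DEFAULT_SELECT_RATE,
            "split": list(DEFAULT_SPLIT),
        },
        "encoder": {
            "n_layers": 6, "d_model": 512, "n_heads": 8, "lambda_b": 0.2,
            "dropout": 0.1, "max_atoms": 32, "ffn_dim": None,
            "n_rbf": 16, "rbf_max": 8.0, "seed": 0,
        },
        "ssl": {
            "include_keep": True,
            "mean_losses": True,
        },
        "train": {
            "epochs": 100, "batch_size": 4, "lr": 2e-3, "warmup_steps": 100,
            "seed": 0, "pretrain_reg_weight": 0.1, "head_hidden": 128,
            "ft_epochs": 20, "ft_batch_size": 20,
        },
    }


def config_from_dict(raw: Dict[str, dict]) -> Tuple[FeaturizeConfig, EncoderConfig,
                                                    PretrainConfig, FinetuneConfig]:
    """Merge a (possibly partial) config dict over the defaults."""
    cfg = default_config()
    for section, values in (raw or {}).items():
        if section not in cfg:
            raise KeyError(f"unknown config section {section!r}")
        for k, v in values.items():
            if k not in cfg[section]:
                raise KeyError(f"unknown config key {section}.{k}")
            cfg[section][k] = v
    f = cfg["featurize"]
    feat = FeaturizeConfig(use_chiral_tokens=f["use_chiral_tokens"],
                           signed_torsions=f["signed_torsions"],
                           nmr_bin_width=f["nmr_bin_width"],
                           nmr_range=tuple(f["nmr_range"]))
    e = cfg["encoder"]
    enc = EncoderConfig(n_layers=e["n_layers"], d_model=e["d_model"],
                        n_heads=e["n_heads"], lambda_b=e["lambda_b"],
                        dropout=e["dropout"], max_atoms=e["max_atoms"],
                        ffn_dim=e["ffn_dim"], n_rbf=e["n_rbf"],
                        rbf_max=e["rbf_max"], seed=e["seed"])
    c, s, t = cfg["corruption"], cfg["ssl"], cfg["train"]
    pt = PretrainConfig(epochs=t["epochs"], batch_size=t["batch_size"], lr=t["lr"],
                        warmup_steps=t["warmup_steps"], select_rate=c["select_rate"],
                        split=tuple(c["split"]), include_keep=s["include_keep"],
                        mean_losses=s["mean_losses"], seed=t["seed"])
    ft = FinetuneConfig(head_hidden=t["head_hidden"], epochs=t["ft_epochs"],
                        batch_size=t["ft_batch_size"], lr=t["lr"],
                        warmup_steps=t["warmup_steps"],
                        pretrain_reg_weight=t["pretrain_reg_weight"], seed=t["seed"])
    return feat, enc, pt, ft


def load_pretrained(path) -> PretrainModel:
    """Rebuild a :class:`PretrainModel` from a checkpoint archive."""
    header, state = load_checkpoint(path)
    enc_cfg = EncoderConfig(**header["config"])
    fdict = header.get("feat_cfg", {})
    feat_cfg = FeaturizeConfig(
        use_chiral_tokens=fdict.get("use_chiral_tokens", True),
        signed_torsions=fdict.get("signed_torsions", False),
        nmr_bin_width=fdict.get("nmr_bin_width", 1.0),
        nmr_range=tuple(fdict.get("nmr_range", (-50.0, 300.0))),
    )
    model = PretrainModel(enc_cfg, feat_cfg)
    model.load_state_dict(state)
    return model
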