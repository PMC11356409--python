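"""Two-phase teacher-student orchestration.

Phase 1 trains one segmentation teacher and one reconstruction autoencoder
per labeled source domain (each on a deterministic 90/10 train/validation
split, keeping the checkpoint with the best validation Dice).  Phase 2 runs
every teacher and autoencoder over the unlabeled target images, fuses the
teachers' soft predictions into per-image pseudo-labels, trains a student
segmenter of the same architecture on those soft labels, and evaluates it
against the held-out target annotations.  The *Merge* baseline instead
pools all source domains into a single teacher.

Target ground-truth masks are only reachable through
``DomainDataset.heldout_masks``, which records every access, so the
no-peeking contract is testable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ganet import GANet, GANetConfig, save_checkpoint
from .losses import LossConfig, multiscale_loss
from .metrics import MetricsReport, evaluate_masks
from .nn import Adam, Tensor
from .synthetic import DomainDataset, generate_benchmark
from .udfusion import (AETrainConfig, Autoencoder, FusionMode, FusionWeights,
                       train_autoencoder, udfusion)
from .io import write_soft_label

logger = logging.getLogger(__name__)


@dataclass
class SATSConfig:
    """All free hyper-parameters of the protocol.

    Defaults follow the full-scale recipe (Adam, initial learning rate
    2e-4 with first/second moment decay 0.9/0.999, batch size 4, 200
    epochs, 90/10 train/validation split); tests and the desk-scale
    benchmark override epochs and dataset size.
    """

    ganet: GANetConfig = field(default_factory=GANetConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    fusion_mode: str = "udfusion"
    epochs: int = 200
    learning_rate: float = 2e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 4
    seed: int = 0
    val_fraction: float = 0.1
    ae_epochs: int | None = None       # default: half the segmenter budget
    binary_entropy: bool = False
    # Student targets: fused pseudo-labels are binarized at this threshold
    # before the Tversky loss.  With soft targets, a confidently-wrong
    # teacher puts a soft floor under the background and the soft-count
    # Tversky index of the all-foreground prediction then exceeds that of
    # the faithful fit, so training collapses; binarizing keeps the fusion
    # weights' decision (where the convex combination crosses 0.5) while
    # restoring a proper objective.  Set to None to train on soft targets.
    student_binarize_threshold: float | None = 0.5

    def resolved_ae_epochs(self) -> int:
        # reconstruction error only measures distribution distance once each
        # autoencoder has reached its own-domain reconstruction floor, so
        # the half-budget rule gets a floor of 40 epochs (the AEs are cheap)
        return max(40, self.epochs // 2) if self.ae_epochs is None \
            else self.ae_epochs

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SATSConfig":
        data = dict(data)
        if "ganet" in data and isinstance(data["ganet"], dict):
            data["ganet"] = GANetConfig(**data["ganet"])
        if "loss" in data and isinstance(data["loss"], dict):
            data["loss"] = LossConfig(**data["loss"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SATSConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TrainedSegmenter:
    model: GANet
    train_losses: list[float]
    val_dice_history: list[float]
    best_val_dice: float


def _split_indices(n: int, val_fraction: float, seed: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng([seed, 86028157])
    order = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
    return order[n_val:], order[:n_val]


def _mean_dice(model: GANet, images: np.ndarray, labels: np.ndarray,
               threshold: float = 0.5) -> float:
    preds = model.predict(images) > threshold
    dices = []
    for p, y in zip(preds, labels):
        y = y > 0.5
        denom = 2 * np.count_nonzero(p & y) + np.count_nonzero(p ^ y)
        dices.append(1.0 if denom == 0
                     else 2 * np.count_nonzero(p & y) / denom)
    return float(np.mean(dices))


def _train_segmenter(images: np.ndarray, labels: np.ndarray,
                     cfg: SATSConfig, stage_seed: int) -> TrainedSegmenter:
    """Shared training loop for teachers, the student and the Merge model.

    ``labels`` may be binary or soft; model selection is by Dice on the
    validation split (labels binarized at 0.5 for the Dice computation).
    """
    n = len(images)
    train_idx, val_idx = _split_indices(n, cfg.val_fraction, stage_seed)
    model = GANet(cfg.ganet, seed=stage_seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    rng = np.random.default_rng([stage_seed, 15485863])
    x_all = np.transpose(images, (0, 3, 1, 2)).astype(np.float32)
    y_all = np.asarray(labels, dtype=np.float32)
    train_losses, val_history = [], []
    best = (-1.0, None)
    for epoch in range(cfg.epochs):
        model.train()
        order = train_idx[rng.permutation(len(train_idx))]
        losses = []
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            opt.zero_grad()
            pyramid = model(Tensor(x_all[idx]))
            loss = multiscale_loss(pyramid, y_all[idx], cfg.loss)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        train_losses.append(float(np.mean(losses)))
        if len(val_idx):
            dice = _mean_dice(model, images[val_idx], y_all[val_idx])
            val_history.append(dice)
            if dice > best[0]:
                best = (dice, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    return TrainedSegmenter(model=model, train_losses=train_losses,
                            val_dice_history=val_history,
                            best_val_dice=best[0] if best[1] is not None
                            else float("nan"))


def train_teacher(dataset: DomainDataset, cfg: SATSConfig
                  ) -> TrainedSegmenter:
    """Train one GANet teacher on a labeled source domain."""
    if not dataset.labeled or dataset.masks is None:
        raise ValueError(
            f"train_teacher requires a labeled dataset; {dataset.name!r} "
            "is unlabeled")
    stage_seed = cfg.seed * 10000 + 1000 + dataset.domain_id
    return _train_segmenter(dataset.images, dataset.masks, cfg, stage_seed)


def train_teachers(sources: list[DomainDataset], cfg: SATSConfig
                   ) -> list[TrainedSegmenter]:
    return [train_teacher(ds, cfg) for ds in sources]


def train_autoencoders(sources: list[DomainDataset], cfg: SATSConfig
                       ) -> list[Autoencoder]:
    models = []
    for ds in sources:
        ae_cfg = AETrainConfig(epochs=cfg.resolved_ae_epochs(),
                               seed=cfg.seed * 10000 + 2000 + ds.domain_id)
        model, _ = train_autoencoder(ds, ae_cfg)
        models.append(model)
    return models


@dataclass
class PseudoLabeledDataset:
    """Target images with fused soft pseudo-labels and fusion diagnostics."""

    source: DomainDataset
    pseudo_labels: np.ndarray            # (N, H, W) float32 in [0, 1]
    weights: list[FusionWeights]
    teacher_predictions: np.ndarray      # (k, N, H, W)

    @property
    def images(self) -> np.ndarray:
        return self.source.images

    def __len__(self) -> int:
        return len(self.pseudo_labels)

    def selected_teacher(self) -> np.ndarray:
        """Per-image argmax of the distribution weight u."""
        return np.array([int(np.argmax(w.u)) for w in self.weights])

    def save(self, out_dir) -> None:
        """Write 16-bit PNG pseudo-labels plus a YAML sidecar of u vectors."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sidecar = []
        for j, (label, w) in enumerate(zip(self.pseudo_labels, self.weights)):
            name = f"{j:04d}.png"
            write_soft_label(label, out_dir / name)
            sidecar.append({
                "image": name,
                "u": [float(x) for x in w.u],
                "distances": None if w.distances is None
                else [float(x) for x in w.distances]})
        with open(out_dir / "fusion_weights.yaml", "w") as fh:
            yaml.safe_dump(sidecar, fh)


def generate_pseudo_labels(teachers: list[TrainedSegmenter | GANet],
                           autoencoders: list[Autoencoder],
                           target: DomainDataset,
                           mode: FusionMode | str = FusionMode.UDFUSION,
                           binary_entropy: bool = False
                           ) -> PseudoLabeledDataset:
    """Fuse every teacher's prediction on each target image via UDFusion."""
    models = [t.model if isinstance(t, TrainedSegmenter) else t
              for t in teachers]
    if len(models) != len(autoencoders):
        raise ValueError(
            f"{len(models)} teachers but {len(autoencoders)} autoencoders")
    preds = np.stack([m.predict(target.images) for m in models])  # (k,N,H,W)
    recons = np.stack([ae.reconstruct(target.images)
                       for ae in autoencoders])                   # (k,N,H,W,3)
    distances = np.mean((recons - target.images[None]) ** 2,
                        axis=(2, 3, 4))                           # (k, N)
    labels = np.empty(preds.shape[1:], dtype=np.float32)
    weights = []
    for j in range(preds.shape[1]):
        fused, w = udfusion(preds[:, j], distances[:, j], mode,
                            binary_entropy=binary_entropy)
        labels[j] = fused
        weights.append(w)
    return PseudoLabeledDataset(source=target, pseudo_labels=labels,
                                weights=weights, teacher_predictions=preds)


def train_student(pseudo: PseudoLabeledDataset, cfg: SATSConfig
                  ) -> TrainedSegmenter:
    """Train the student GANet against the fused pseudo-labels."""
    if len(pseudo) != len(pseudo.images):
        raise ValueError("every target image needs a pseudo-label")
    stage_seed = cfg.seed * 10000 + 3000
    labels = pseudo.pseudo_labels
    if cfg.student_binarize_threshold is not None:
        labels = (labels > cfg.student_binarize_threshold).astype(np.float32)
    return _train_segmenter(pseudo.images, labels, cfg, stage_seed)


def train_merged_baseline(sources: list[DomainDataset], cfg: SATSConfig
                          ) -> TrainedSegmenter:
    """Single teacher on all source domains pooled (the Merge ablation)."""
    for ds in sources:
        if not ds.labeled or ds.masks is None:
            raise ValueError(f"source {ds.name!r} must be labeled")
    images = np.concatenate([ds.images for ds in sources])
    masks = np.concatenate([ds.masks for ds in sources])
    stage_seed = cfg.seed * 10000 + 4000
    return _train_segmenter(images, masks, cfg, stage_seed)


def evaluate_model(model: GANet | TrainedSegmenter, dataset: DomainDataset,
                   threshold: float = 0.5,
                   masks: np.ndarray | None = None) -> MetricsReport:
    """Seven metrics of a segmenter on a labeled dataset.

    For the unlabeled target, pass the held-out masks explicitly (obtained
    through ``dataset.heldout_masks(...)`` so the access is on record).
    """
    if isinstance(model, TrainedSegmenter):
        model = model.model
    if masks is None:
        if not dataset.labeled or dataset.masks is None:
            raise ValueError(
                f"dataset {dataset.name!r} is unlabeled; pass held-out "
                "masks explicitly")
        masks = dataset.masks
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    preds = (model.predict(dataset.images) > threshold).astype(np.uint8)
    return evaluate_masks(preds, masks)


@dataclass
class ExperimentReport:
    config: dict
    teacher_val_dice: list[float]
    teacher_metrics: list[dict]
    fusion_mode: str
    mean_u: list[float]
    selectivity: float | None
    student_metrics: dict
    stage_seconds: dict[str, float]
    target_mask_accesses: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


@dataclass
class BenchmarkSpec:
    """Synthetic benchmark dimensions for :func:`run_sats`."""

    k: int = 3
    n_per_domain: int = 60
    height: int = 64
    width: int = 64


def run_sats(cfg: SATSConfig, datasets: list[DomainDataset] | None = None,
             benchmark: BenchmarkSpec | None = None,
             out_dir=None, dry_run: bool = False) -> ExperimentReport | None:
    """Execute the full protocol and return a report.

    ``datasets`` is k labeled sources followed by the unlabeled target; if
    omitted, a synthetic benchmark is generated from ``benchmark`` and the
    config seed.  ``dry_run`` validates configuration and data without
    training.
    """
    timings: dict[str, float] = {}
    if datasets is None:
        spec = benchmark or BenchmarkSpec()
        t0 = time.perf_counter()
        datasets = generate_benchmark(spec.k, spec.n_per_domain, spec.height,
                                      spec.width, master_seed=cfg.seed)
        timings["synthesize"] = time.perf_counter() - t0
    sources, target = datasets[:-1], datasets[-1]
    if target.labeled:
        raise ValueError("last dataset must be the unlabeled target")
    for ds in sources:
        if not ds.labeled:
            raise ValueError(f"source {ds.name!r} must be labeled")
    FusionMode(cfg.fusion_mode)  # validate early
    if dry_run:
        logger.info("dry run: config and %d datasets validated",
                    len(datasets))
        return None

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out_dir / "config.yaml")

    t0 = time.perf_counter()
    if cfg.fusion_mode == "merge":
        merged = train_merged_baseline(sources, cfg)
        teachers = [merged]
        timings["train_teachers"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        aes = train_autoencoders(
            [DomainDataset(domain_id=0, name="merged", style=sources[0].style,
                           images=np.concatenate(
                               [ds.images for ds in sources]),
                           masks=None, labeled=False,
                           sample_seeds=[])], cfg)
        fusion_mode = FusionMode.MEAN   # single model; weights are trivial
    else:
        teachers = train_teachers(sources, cfg)
        timings["train_teachers"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        aes = train_autoencoders(sources, cfg)
        fusion_mode = FusionMode(cfg.fusion_mode)
    timings["train_autoencoders"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pseudo = generate_pseudo_labels(teachers, aes, target, fusion_mode,
                                    binary_entropy=cfg.binary_entropy)
    timings["pseudo_labels"] = time.perf_counter() - t0
    if out_dir is not None:
        pseudo.save(out_dir / "pseudo_labels")

    t0 = time.perf_counter()
    student = train_student(pseudo, cfg)
    timings["train_student"] = time.perf_counter() - t0
    assert target.mask_access_log == [], \
        "target ground truth was read during training"

    t0 = time.perf_counter()
    held_out = target.heldout_masks("evaluation")
    student_report = evaluate_model(student, target, masks=held_out)
    teacher_reports = [evaluate_model(t, target, masks=held_out)
                       for t in teachers]
    timings["evaluate"] = time.perf_counter() - t0

    mean_u = np.mean([w.u for w in pseudo.weights], axis=0)
    selectivity = None
    if target.nearest_source is not None and len(teachers) == len(sources):
        ids = np.array([ds.domain_id for ds in sources])
        chosen = ids[pseudo.selected_teacher()]
        selectivity = float(np.mean(chosen == target.nearest_source))

    report = ExperimentReport(
        config=cfg.to_dict(),
        teacher_val_dice=[t.best_val_dice for t in teachers],
        teacher_metrics=[r.to_dict() for r in teacher_reports],
        fusion_mode=str(fusion_mode.value),
        mean_u=[float(x) for x in mean_u],
        selectivity=selectivity,
        student_metrics=student_report.to_dict(),
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
        target_mask_accesses=list(target.mask_access_log),
    )
    if out_dir is not None:
        report.to_json(out_dir / "report.json")
        for i, t in enumerate(teachers):
            save_checkpoint(t.model, out_dir / f"teacher_{i + 1}.npz")
        save_checkpoint(student.model, out_dir / "student.npz")
        student_report.to_csv(out_dir / "student_per_image_metrics.csv")
    return report
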