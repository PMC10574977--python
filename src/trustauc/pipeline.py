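"""End-to-end orchestration: pre-train, fine-tune, select, evaluate.

A run executes up to three stages on a manifest-backed dataset:

1. optional contrastive self-supervised pre-training of the backbone on
   the (unlabeled) train images;
2. supervised fine-tuning on the train split with a class-balanced
   validation split carved out for per-epoch monitoring and the
   five-criterion checkpoint set;
3. evaluation of the selected checkpoint on the held-out test split:
   confusion metrics at the F1-calibrated threshold, exact ROC AUC, and
   the positive-class trust score.

The three supported arms mirror an ablation ladder: "SL" (cross-entropy,
no SSL), "SL+SSL" (cross-entropy after contrastive pre-training) and
"SL+SSL+AUC" (AUC margin fine-tuning after pre-training).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import CheckpointSet, FinetuneConfig, finetune
from .data import balanced_validation_split, kfold_splits, read_manifest
from .evalviz import confusion_counts, confusion_metrics, roc_auc
from .ssl import AugmentationPolicy, SSLConfig, pretrain_encoder
from .trust import TrustScorer

__all__ = [
    "RunConfig",
    "RunArtifacts",
    "ARMS",
    "run",
    "select_model",
    "ablation",
    "cross_validate",
]

logger = logging.getLogger("trustauc")

# arm name -> (use_ssl, finetune_loss)
ARMS = {
    "SL": (False, "cross_entropy"),
    "SL+SSL": (True, "cross_entropy"),
    "SL+SSL+AUC": (True, "auc_margin"),
}


@dataclass
class RunConfig:
    """Fully-resolved configuration of one pipeline run."""

    manifest: str
    out_dir: str
    image_side: int = 32
    use_ssl: bool = True
    finetune_loss: str = "auc_margin"
    init_weights: str | None = None  # None/"random" or a checkpoint path
    selection_criterion: str = "best_val_f1"
    val_fraction: float = 0.10
    trust_alpha: float = 1.0
    trust_beta: float = 1.0
    seed: int = 0
    log_level: str = "INFO"
    ssl: SSLConfig = field(default_factory=SSLConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)

    def __post_init__(self):
        arm = (self.use_ssl, self.finetune_loss)
        if arm not in ARMS.values():
            raise ValueError(
                f"unsupported arm (use_ssl={self.use_ssl}, loss={self.finetune_loss}); "
                f"valid arms: {ARMS}"
            )

    @property
    def arm(self) -> str:
        return next(k for k, v in ARMS.items() if v == (self.use_ssl, self.finetune_loss))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ssl_d = d.pop("ssl", {}) or {}
        ft_d = d.pop("finetune", {}) or {}
        if "encoder_widths" in ft_d:
            ft_d["encoder_widths"] = tuple(ft_d["encoder_widths"])
        return cls(ssl=SSLConfig(**ssl_d), finetune=FinetuneConfig(**ft_d), **d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, tuple):
                return [clean(x) for x in v]
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            return v

        d = clean(dataclasses.asdict(self))
        d["arm"] = self.arm
        return d


@dataclass
class RunArtifacts:
    out_dir: Path
    metrics: dict
    trust: dict
    checkpoint_paths: dict[str, str]
    selected_checkpoint: str
    history_csv: str
    config_path: str
    log_path: str
    stages_run: list[str]


def _setup_logging(out_dir: Path, level: str) -> logging.Handler:
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    return handler


def _evaluate(clf, dataset, alpha, beta):
    """Test-split evaluation with val-calibrated threshold and trust."""
    val = dataset.subset("val")
    test = dataset.subset("test")
    if len(test) == 0:
        raise ValueError("dataset has no test split to evaluate on")
    s_val = clf.scores(val.load())
    scorer = TrustScorer(alpha=alpha, beta=beta).fit(s_val, val.labels())
    s_test = clf.scores(test.load())
    y_test = test.labels()
    t = scorer.threshold_
    pred = (s_test >= t).astype(int)
    rep = confusion_metrics(confusion_counts(pred, y_test))
    rep.auc = roc_auc(s_test, y_test)
    trust_rep = scorer.report([r.id for r in test.records], s_test, y_test)
    rep.trust_pos = trust_rep.positive_trust
    return rep, trust_rep, scorer.threshold_


def run(config: RunConfig) -> RunArtifacts:
    """Execute one configured run end to end and write all artifacts."""
    out_dir = Path(config.out_dir)
    handler = _setup_logging(out_dir, config.log_level)
    stages: list[str] = []
    try:
        logger.info("run start: arm=%s seed=%d", config.arm, config.seed)
        dataset = read_manifest(config.manifest, image_side=config.image_side)
        train_ds, val_ds = balanced_validation_split(
            dataset, config.val_fraction, config.seed
        )
        work = dataclasses.replace(
            dataset, records=train_ds.records + val_ds.records
            + [r for r in dataset.records if r.split == "test"]
        )
        logger.info(
            "splits: train=%s val=%s test=%s",
            train_ds.counts(), val_ds.counts(), work.counts("test"),
        )

        init_state = None
        if config.init_weights and config.init_weights != "random":
            init_state = config.init_weights
        if config.use_ssl:
            stages.append("ssl_pretrain")
            ssl_cfg = dataclasses.replace(config.ssl, seed=config.seed)
            ssl_path, ssl_hist = pretrain_encoder(
                train_ds, AugmentationPolicy(), ssl_cfg, out_dir / "ssl"
            )
            logger.info("ssl pre-training done: final loss %.4f", ssl_hist[-1])
            init_state = str(ssl_path)

        stages.append("finetune")
        ft_cfg = dataclasses.replace(
            config.finetune,
            loss=config.finetune_loss,
            image_side=config.image_side,
            seed=config.seed,
        )
        clf, checkpoints, history = finetune(
            work, ft_cfg, init_encoder_state=init_state, out_dir=out_dir / "checkpoints"
        )
        logger.info("fine-tuning done: %d epochs", len(history))

        stages.append("evaluate")
        entry = select_model(checkpoints, config.selection_criterion)
        clf.load_snapshot(entry["snapshot"])
        logger.info(
            "selected checkpoint %s (epoch %d)",
            config.selection_criterion, entry["epoch"],
        )
        rep, trust_rep, threshold = _evaluate(
            clf, work, config.trust_alpha, config.trust_beta
        )
        logger.info(
            "test metrics: acc=%.3f auc=%.3f f1=%.3f trust=%.3f",
            rep.accuracy, rep.auc, rep.f1_pos, rep.trust_pos,
        )

        metrics = rep.to_dict()
        metrics["threshold"] = threshold
        metrics["selection_criterion"] = config.selection_criterion
        metrics["arm"] = config.arm
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        trust_rep.to_json(out_dir / "trust.json")
        trust_rep.per_sample_csv(out_dir / "trust_per_sample.csv")
        config_path = out_dir / "config_resolved.yaml"
        config_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))

        return RunArtifacts(
            out_dir=out_dir,
            metrics=metrics,
            trust=json.loads((out_dir / "trust.json").read_text()),
            checkpoint_paths={
                c: e.get("path", "") for c, e in checkpoints.entries.items()
            },
            selected_checkpoint=entry.get("path", ""),
            history_csv=str(out_dir / "checkpoints" / "history.csv"),
            config_path=str(config_path),
            log_path=str(out_dir / "run.log"),
            stages_run=stages,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


def select_model(checkpoints: CheckpointSet, criterion: str) -> dict:
    """Look up the checkpoint recorded under a selection criterion.

    Ties during training were broken toward the earlier epoch, so the
    returned entry is the first epoch achieving the criterion's best value.
    """
    return checkpoints[criterion]


def ablation(config: RunConfig, out_dir=None) -> pd.DataFrame:
    """Run the three arms on one dataset/seed and tabulate them.

    Output rows SL / SL+SSL / SL+SSL+AUC with per-class precision and
    sensitivity plus the trust score. If an arm fails, the completed rows
    are still written before the error propagates.
    """
    out_dir = Path(out_dir if out_dir is not None else config.out_dir)
    rows = []
    try:
        for arm, (use_ssl, loss) in ARMS.items():
            cfg = dataclasses.replace(
                config,
                use_ssl=use_ssl,
                finetune_loss=loss,
                out_dir=str(out_dir / arm.replace("+", "_")),
            )
            art = run(cfg)
            m = art.metrics
            rows.append(
                {
                    "arm": arm,
                    "precision_pos": m["precision_pos"],
                    "precision_neg": m["precision_neg"],
                    "sensitivity_pos": m["sensitivity_pos"],
                    "sensitivity_neg": m["sensitivity_neg"],
                    "auc": m["auc"],
                    "trust": m["trust_pos"],
                }
            )
    except Exception as exc:
        if rows:
            pd.DataFrame(rows).to_csv(out_dir / "ablation_partial.csv", index=False)
        raise RuntimeError(
            f"ablation arm failed after {len(rows)} completed arm(s): {exc}"
        ) from exc
    df = pd.DataFrame(rows)
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / "ablation.csv", index=False)
    return df


def _fmt_pm(values: np.ndarray) -> str:
    mean = float(np.mean(values))
    half_range_pct = float((np.max(values) - np.min(values)) / 2.0 * 100.0)
    return f"{mean:.3f}±{half_range_pct:.1f}%"


def cross_validate(config: RunConfig, k: int = 5) -> dict:
    """k-fold cross-validated fine-tuning, each fold evaluated on test.

    Folds are class-stratified partitions of the train split and govern
    training/validation only; the fixed test split is the common
    evaluation target. With SSL enabled the backbone is pre-trained once
    on the full train split (labels unused) and shared across folds.
    Returns per-fold metrics plus a mean +/- half-range summary (the
    dispersion convention is recorded in the output metadata).
    """
    out_dir = Path(config.out_dir)
    handler = _setup_logging(out_dir, config.log_level)
    try:
        dataset = read_manifest(config.manifest, image_side=config.image_side)
        train_all = dataset.subset("train")
        test_recs = [r for r in dataset.records if r.split == "test"]
        folds = kfold_splits(train_all, k, config.seed)

        init_state = None
        if config.use_ssl:
            ssl_cfg = dataclasses.replace(config.ssl, seed=config.seed)
            ssl_path, _ = pretrain_encoder(
                train_all, AugmentationPolicy(), ssl_cfg, out_dir / "ssl"
            )
            init_state = str(ssl_path)

        per_fold = []
        for i, (tr, va) in enumerate(folds):
            logger.info("fold %d/%d: train=%s val=%s", i + 1, k, tr.counts(), va.counts())
            work = dataclasses.replace(
                dataset, records=tr.records + va.records + test_recs
            )
            ft_cfg = dataclasses.replace(
                config.finetune,
                loss=config.finetune_loss,
                image_side=config.image_side,
                seed=config.seed + i,
            )
            clf, checkpoints, _ = finetune(
                work, ft_cfg, init_encoder_state=init_state,
                out_dir=out_dir / f"fold{i}",
            )
            entry = select_model(checkpoints, config.selection_criterion)
            clf.load_snapshot(entry["snapshot"])
            rep, _, _ = _evaluate(clf, work, config.trust_alpha, config.trust_beta)
            row = rep.to_dict()
            row["fold"] = i
            per_fold.append(row)

        metric_names = [
            "precision_pos", "precision_neg", "sensitivity_pos",
            "sensitivity_neg", "accuracy", "f1_pos", "auc", "trust_pos",
        ]
        summary_fmt = {}
        summary_mean = {}
        for mname in metric_names:
            vals = np.array([row[mname] for row in per_fold], dtype=float)
            summary_fmt[mname] = _fmt_pm(vals)
            summary_mean[mname] = float(np.mean(vals))
        result = {
            "k": k,
            "per_fold": per_fold,
            "summary": summary_fmt,
            "summary_mean": summary_mean,
            "dispersion": "half-range (max-min)/2, percent of metric scale",
        }
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "cv_summary.json").write_text(json.dumps(result, indent=2))
        pd.DataFrame(per_fold).to_csv(out_dir / "cv_per_fold.csv", index=False)
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()
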