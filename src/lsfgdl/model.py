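"""High-level modelling interface: BorylationModel -> fit() -> BorylationResults.

This is the front door of the package, shaped like a statsmodels model:
construct a model from reaction records (or a SURF file), call ``fit`` to
train the configured network, and receive a results object carrying the
fitted network, training history, test-set metrics and a ``summary()``
table.  The lower-level modules (surf, graphs, conditions, networks,
training, synthetic) remain available for custom pipelines.

Example
-------
>>> from lsfgdl import BorylationModel, ModelConfig, TrainConfig
>>> from lsfgdl.synthetic import SyntheticSpec, make_dataset
>>> records, truth = make_dataset(SyntheticSpec(n_substrates=12, seed=7))
>>> model = BorylationModel(records, config=ModelConfig(
...     architecture="GNN", graph_variant="2D", task="yield",
...     hidden_dim=32, embed_dim=16, post_pool_dim=32, mlp_hidden=32))
>>> res = model.fit(TrainConfig(learning_rate=1e-3, max_epochs=15, seed=0))
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .conditions import (
    EXPERIMENTAL_FIELDS,
    LITERATURE_FIELDS,
    ConditionVocabulary,
    fit_vocabulary,
)
from .graphs import DEFAULT_CHARGE_PROVIDER
from .networks import BorylationNet, ECFP4NN, ModelConfig, count_parameters
from .surf import ReactionRecord, read_surf
from .training import (
    SplitPlan,
    TrainConfig,
    featurize_baseline,
    featurize_reactions,
    featurize_regio,
    make_split,
    metric_classification,
    metric_regression,
    predict,
    predict_ensemble,
    predict_ensemble_batch,
    roc_auc,
    train,
    train_val_split,
)

__all__ = ["BorylationModel", "BorylationResults"]


class BorylationModel:
    """A borylation prediction model bound to a reaction dataset.

    Parameters
    ----------
    records : list of ReactionRecord
        The dataset (experimental- or literature-regime SURF rows).
    config : ModelConfig, optional
        Architecture and dimensions; defaults to production-scale GTNN3DQM
        for yield prediction.
    condition_fields : tuple of str, optional
        Which categorical fields to one-hot encode; inferred from the
        record sources when omitted (ligand+solvent for experimental data,
        plus reagent+catalyst for literature data).
    threshold : float
        Conversion threshold (%) for the binary task.
    n_conformers : int
        Conformer-ensemble size for 3D variants.
    """

    def __init__(
        self,
        records: list[ReactionRecord],
        config: ModelConfig | None = None,
        condition_fields: tuple[str, ...] | None = None,
        threshold: float = 1.0,
        n_conformers: int = 10,
        charge_provider: str = DEFAULT_CHARGE_PROVIDER,
    ):
        if not records:
            raise ValueError("cannot model an empty dataset")
        self.records = list(records)
        self.config = config or ModelConfig()
        if condition_fields is None:
            literature = all(r.source == "literature" for r in records)
            condition_fields = LITERATURE_FIELDS if literature else EXPERIMENTAL_FIELDS
        self.vocab: ConditionVocabulary = fit_vocabulary(records, condition_fields)
        self.threshold = threshold
        self.n_conformers = n_conformers
        self.charge_provider = charge_provider

    @classmethod
    def from_surf(cls, path, **kwargs) -> "BorylationModel":
        return cls(read_surf(path), **kwargs)

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        train_config: TrainConfig | None = None,
        split: SplitPlan | None = None,
        val_fraction: float = 0.15,
        seed: int | None = None,
    ) -> "BorylationResults":
        """Train on one train/test split and evaluate on the held-out fold.

        The first fold of `split` (default: random 4-fold) defines the test
        set; an early-stopping validation subset is carved from the
        training side.
        """
        tcfg = train_config or TrainConfig()
        if seed is not None:
            tcfg.seed = seed
        split = split or SplitPlan(mode="random_kfold", k=4)
        folds = make_split(self.records, split, tcfg.seed)
        train_all, test_idx = folds[0]
        tr_idx, val_idx = train_val_split(train_all, val_fraction, tcfg.seed)

        items = self._featurize(self.records, tcfg.seed)
        by_id = {it.rxn_id: it for it in items}
        ids = [r.rxn_id for r in self.records]
        pick = lambda idx: [by_id[ids[i]] for i in idx if ids[i] in by_id]
        train_items, val_items, test_items = pick(tr_idx), pick(val_idx), pick(test_idx)
        if not train_items or not val_items or not test_items:
            raise ValueError("a split side is empty after label filtering")

        net = self._build_network(tcfg.seed)
        fit_info = train(net, train_items, val_items, tcfg)
        metrics, predictions = self._evaluate(net, test_items)
        return BorylationResults(
            model=self,
            network=net,
            train_config=tcfg,
            history=fit_info["history"],
            best_epoch=fit_info["best_epoch"],
            metrics=metrics,
            predictions=predictions,
            n_train=len(train_items),
            n_val=len(val_items),
            n_test=len(test_items),
        )

    def fit_cv(
        self,
        train_config: TrainConfig | None = None,
        k: int = 4,
        val_fraction: float = 0.15,
    ) -> dict:
        """Nested k-fold cross-validation.

        Outer folds define the test sets; inside each outer training side an
        inner split provides the early-stopping validation set.  Test
        predictions are pooled over all outer folds, so every reaction in
        the dataset receives an out-of-fold prediction; pooled metrics and
        the per-fold results are returned.
        """
        tcfg = train_config or TrainConfig()
        folds = make_split(self.records, SplitPlan("nested_kfold", k=k), tcfg.seed)
        items = self._featurize(self.records, tcfg.seed)
        by_id = {it.rxn_id: it for it in items}
        ids = [r.rxn_id for r in self.records]
        pooled_pred, pooled_true, per_fold = [], [], []
        for fold_no, (train_all, test_idx) in enumerate(folds):
            tr_idx, val_idx = train_val_split(train_all, val_fraction, tcfg.seed + fold_no)
            pick = lambda idx: [by_id[ids[i]] for i in idx if ids[i] in by_id]
            net = self._build_network(tcfg.seed + fold_no)
            train(net, pick(tr_idx), pick(val_idx), tcfg)
            metrics, preds = self._evaluate(net, pick(test_idx))
            per_fold.append(metrics)
            if self.config.task == "regio":
                pooled_pred.extend(preds["atom_scores"])
                pooled_true.extend(preds["atom_labels"])
            else:
                pooled_pred.extend(preds["prediction"])
                pooled_true.extend(preds["target"])
        pred, true = np.asarray(pooled_pred), np.asarray(pooled_true)
        if self.config.task == "yield":
            r, mae = metric_regression(100 * pred, 100 * true)
            pooled = {"pearson_r": r, "mae_percent": mae, "n": len(pred)}
        else:
            pooled = metric_classification(pred > 0.5, true > 0.5).as_dict()
            pooled["auc"] = roc_auc(pred, true > 0.5)
        return {"pooled": pooled, "folds": per_fold,
                "predictions": pred.tolist(), "targets": true.tolist()}

    # -------------------------------------------------------------- internals
    def _build_network(self, seed: int):
        if self.config.architecture == "ECFP4NN":
            return ECFP4NN(
                self.config,
                ligand_width=len(self.vocab.categories["ligand"]),
                solvent_width=len(self.vocab.categories["solvent"]),
                seed=seed,
            )
        return BorylationNet(
            self.config,
            condition_width=0 if self.config.task == "regio" else self.vocab.width,
            seed=seed,
        )

    def _featurize(self, records, seed):
        if self.config.task == "regio":
            return featurize_regio(records, self.config, self.n_conformers, seed)
        if self.config.architecture == "ECFP4NN":
            return featurize_baseline(records, self.config, self.vocab, self.threshold)
        return featurize_reactions(
            records, self.config, self.vocab, self.threshold, self.n_conformers, seed
        )

    def _evaluate(self, net, test_items):
        task = self.config.task
        if task == "regio":
            mean, _ = predict_ensemble_batch(net, test_items)
            mask = np.concatenate([it.candidate_mask for it in test_items])
            y = np.concatenate([it.labels for it in test_items])[mask]
            s = mean[mask]
            report = metric_classification(s > 0.5, y > 0.5)
            metrics = report.as_dict()
            metrics["auc"] = roc_auc(s, y > 0.5)
            preds = {"atom_scores": s.tolist(), "atom_labels": y.astype(int).tolist()}
            return metrics, preds
        means, stds = predict_ensemble_batch(net, test_items)
        targets = np.array([it.target for it in test_items])
        preds = {
            "rxn_id": [it.rxn_id for it in test_items],
            "prediction": means.tolist(),
            "prediction_std": stds.tolist(),
            "target": targets.tolist(),
        }
        if task == "yield":
            r, mae = metric_regression(100 * means, 100 * targets)
            return {"pearson_r": r, "mae_percent": mae, "n": len(test_items)}, preds
        report = metric_classification(means > 0.5, targets > 0.5)
        metrics = report.as_dict()
        metrics["auc"] = roc_auc(means, targets > 0.5)
        return metrics, preds


@dataclass
class BorylationResults:
    """Outcome of :meth:`BorylationModel.fit`."""

    model: BorylationModel
    network: BorylationNet
    train_config: TrainConfig
    history: list[dict]
    best_epoch: int
    metrics: dict
    predictions: dict
    n_train: int
    n_val: int
    n_test: int
    _extra: dict = field(default_factory=dict)

    # ------------------------------------------------------------- reporting
    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Borylation model results",
            "=" * 58,
            f"architecture:      {cfg.architecture}{cfg.graph_variant or ''}",
            f"task:              {cfg.task}",
            f"trainable params:  {count_parameters(self.network):,}",
            f"n train/val/test:  {self.n_train}/{self.n_val}/{self.n_test}",
            f"best epoch:        {self.best_epoch} of {len(self.history)}",
            f"seed:              {self.train_config.seed}",
            "-" * 58,
        ]
        for key, value in self.metrics.items():
            if isinstance(value, float):
                lines.append(f"{key + ':':<22}{value:.3f}")
            else:
                lines.append(f"{key + ':':<22}{value}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def predict(self, records: list[ReactionRecord], seed: int | None = None):
        """Ensemble predictions (mean, std) for new reactions, in the task's
        reporting units (% for yield, probability for binary)."""
        items = self.model._featurize(records, seed if seed is not None else self.train_config.seed)
        means, stds = [], []
        for it in items:
            m, sd = predict_ensemble(self.network, it)
            means.append(m)
            stds.append(sd)
        means, stds = np.asarray(means, dtype=object), np.asarray(stds, dtype=object)
        if self.model.config.task == "yield":
            means = np.array([100 * m for m in means], dtype=object)
            stds = np.array([100 * s for s in stds], dtype=object)
        return means, stds

    def plot_history(self, ax=None):
        """Training loss and validation MAE per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = [h["epoch"] for h in self.history]
        ax.plot(epochs, [h["train_loss"] for h in self.history], label="train loss")
        ax.plot(epochs, [h["val_mae"] for h in self.history], label="validation MAE")
        ax.plot(
            epochs, [h["smoothed_val_mae"] for h in self.history],
            label="smoothed validation MAE", linestyle="--",
        )
        ax.axvline(self.best_epoch, color="grey", alpha=0.5)
        ax.set_xlabel("epoch")
        ax.legend()
        return ax

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_config": self.model.config.to_dict(),
                "metrics": self.metrics,
                "best_epoch": self.best_epoch,
                "n_train": self.n_train,
                "n_val": self.n_val,
                "n_test": self.n_test,
            },
            indent=1,
        )
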