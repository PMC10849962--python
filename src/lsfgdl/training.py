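"""Dataset featurization, splits, the training loop and evaluation metrics.

Training follows the production schedule: Adam at learning rate 1e-4,
batch size 16, mean-squared-error loss, a 0.5 learning-rate decay applied
after every 100 epochs, and early stopping on the exponentially smoothed
(factor 0.9) validation mean absolute error within a 1,000-epoch budget.
For 3D graph variants one conformer is drawn at random per molecule at
each training step; test-time predictions average over the full
ten-conformer ensemble and report the ensemble mean and population
standard deviation.

Yields are trained on the [0, 1] fraction scale and reported in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .autodiff import Tensor
from .conditions import ConditionVocabulary, encode_conditions
from .graphs import MolGraph, build_graph, generate_conformers
from .networks import BorylationNet, GraphBatch, ModelConfig
from .nn import Adam
from .surf import ReactionRecord, binarize_outcome, extract_regio_labels

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "MetricsReport",
    "ReactionItem",
    "RegioItem",
    "BaselineItem",
    "featurize_reactions",
    "featurize_regio",
    "featurize_baseline",
    "make_split",
    "train_val_split",
    "train",
    "predict",
    "predict_ensemble",
    "predict_ensemble_batch",
    "metric_regression",
    "metric_classification",
    "fscore_from_rates",
    "evaluate_thresholds",
    "run_repeats",
]


@dataclass
class TrainConfig:
    """Optimizer and schedule hyperparameters (defaults = production scale)."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    loss: str = "mse"
    lr_decay_factor: float = 0.5
    lr_decay_epochs: int = 100
    smoothing_factor: float = 0.9
    max_epochs: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "batch_size", "lr_decay_factor",
                     "lr_decay_epochs", "smoothing_factor", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TrainConfig.{name} must be positive")


@dataclass
class SplitPlan:
    """How to partition reactions into folds.

    * random_kfold: k balanced folds, shuffled under the seed.
    * nested_kfold: the same outer folds; each outer training side is
      further split into train/early-stopping-validation, and test
      predictions are pooled over all outer folds (see
      BorylationModel.fit_cv) so the whole dataset is visualized.
    * substrate_holdout: all reactions of each held-out substrate go to the
      test side together — no substrate ever straddles the split.
    """

    mode: str = "random_kfold"
    k: int = 4
    holdout_substrates: list[str] | None = None

    def __post_init__(self):
        if self.mode not in ("random_kfold", "nested_kfold", "substrate_holdout"):
            raise ValueError(f"unknown split mode {self.mode!r}")


# ------------------------------------------------------------- featurization


@dataclass
class ReactionItem:
    """One reaction, featurized: graphs (one per conformer for 3D), condition
    vector, scalar target on the training scale."""

    rxn_id: str
    substrate: str
    graphs: list[MolGraph]
    condition: np.ndarray
    target: float


@dataclass
class BaselineItem:
    """One reaction for the fingerprint baseline: ECFP4 + condition blocks."""

    rxn_id: str
    substrate: str
    fingerprint: np.ndarray
    ligand_onehot: np.ndarray
    solvent_onehot: np.ndarray
    target: float
    graphs: tuple = (None,)  # conformer-independent, like a 2D variant


@dataclass
class RegioItem:
    """One substrate with per-atom reactive labels and the candidate mask."""

    rxn_id: str
    substrate: str
    graphs: list[MolGraph]
    labels: np.ndarray  # (n_atoms,) 0/1
    candidate_mask: np.ndarray  # (n_atoms,) bool


class _GraphCache:
    """Per-substrate conformers and graphs, built once per dataset."""

    def __init__(self, cfg: ModelConfig, n_conformers: int, seed: int):
        self.cfg = cfg
        self.n_conformers = n_conformers
        self.seed = seed
        self._store: dict[str, list[MolGraph]] = {}

    def graphs(self, smiles: str) -> list[MolGraph]:
        if smiles not in self._store:
            cfg = self.cfg
            if cfg.is_3d:
                cs = generate_conformers(smiles, n=self.n_conformers, seed=self.seed,
                                         molecule_id=smiles)
                self._store[smiles] = [
                    build_graph(smiles, cfg.graph_variant, conformer=c, conformer_id=i,
                                n_frequencies=cfg.n_frequencies)
                    for i, c in enumerate(cs.coords)
                ]
            else:
                self._store[smiles] = [build_graph(smiles, cfg.graph_variant)]
        return self._store[smiles]


def featurize_reactions(
    records: list[ReactionRecord],
    cfg: ModelConfig,
    vocab: ConditionVocabulary,
    threshold: float = 1.0,
    n_conformers: int = 10,
    seed: int = 0,
) -> list[ReactionItem]:
    """Featurize records for the yield or binary task.

    Yield targets are the annotated yields on the fraction scale; records
    with missing yields are dropped for the yield task and, for the binary
    task, kept only when they carry an explicit outcome flag.
    """
    cache = _GraphCache(cfg, n_conformers, seed)
    items = []
    for r in records:
        if cfg.task == "yield":
            if r.yield_percent is None:
                continue
            target = r.yield_percent / 100.0
        elif cfg.task == "binary":
            outcome = r.outcome
            if outcome is None:
                outcome = binarize_outcome(r.yield_percent, threshold)
            if outcome is None:
                continue
            target = float(outcome)
        else:
            raise ValueError("featurize_reactions handles the yield/binary tasks only")
        items.append(
            ReactionItem(r.rxn_id, r.substrate, cache.graphs(r.substrate),
                         encode_conditions(r, vocab), target)
        )
    return items


def featurize_baseline(
    records: list[ReactionRecord],
    cfg: ModelConfig,
    vocab: ConditionVocabulary,
    threshold: float = 1.0,
) -> list[BaselineItem]:
    """Featurize records for the ECFP4NN baseline (yield/binary tasks)."""
    from .networks import ecfp4

    lig_lo = vocab.offsets["ligand"]
    lig_hi = lig_lo + len(vocab.categories["ligand"])
    sol_lo = vocab.offsets["solvent"]
    sol_hi = sol_lo + len(vocab.categories["solvent"])
    fp_cache: dict[str, np.ndarray] = {}
    items = []
    for r in records:
        if cfg.task == "yield":
            if r.yield_percent is None:
                continue
            target = r.yield_percent / 100.0
        else:
            outcome = r.outcome
            if outcome is None:
                outcome = binarize_outcome(r.yield_percent, threshold)
            if outcome is None:
                continue
            target = float(outcome)
        if r.substrate not in fp_cache:
            fp_cache[r.substrate] = ecfp4(r.substrate, cfg.fingerprint_dim)
        vec = encode_conditions(r, vocab)
        items.append(
            BaselineItem(r.rxn_id, r.substrate, fp_cache[r.substrate],
                         vec[lig_lo:lig_hi], vec[sol_lo:sol_hi], target)
        )
    return items


def featurize_regio(
    records: list[ReactionRecord],
    cfg: ModelConfig,
    n_conformers: int = 10,
    seed: int = 0,
) -> list[RegioItem]:
    """Featurize records for per-atom regioselectivity classification."""
    cache = _GraphCache(cfg, n_conformers, seed)
    items = []
    for r in records:
        labels = extract_regio_labels(r.substrate, r.products, r.rxn_id)
        y = np.array([1.0 if lab.is_reactive else 0.0 for lab in labels])
        mask = np.array([lab.is_candidate for lab in labels], dtype=bool)
        items.append(RegioItem(r.rxn_id, r.substrate, cache.graphs(r.substrate), y, mask))
    return items


# --------------------------------------------------------------------- splits


def make_split(records, plan: SplitPlan, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_indices, test_indices) per fold, deterministic under seed."""
    n = len(records)
    substrates = np.array([r.substrate for r in records])
    if plan.mode in ("random_kfold", "nested_kfold"):
        if plan.k > n:
            raise ValueError(f"k={plan.k} exceeds dataset size {n}")
        kf = KFold(n_splits=plan.k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in kf.split(np.arange(n))]
    # substrate holdout
    if plan.holdout_substrates:
        held = [set(h) if not isinstance(h, str) else {h} for h in [plan.holdout_substrates]][0]
        test = np.flatnonzero(np.isin(substrates, sorted(held)))
        train = np.flatnonzero(~np.isin(substrates, sorted(held)))
        if len(test) == 0:
            raise ValueError("no reactions match the held-out substrates")
        return [(train, test)]
    unique = np.array(sorted(set(substrates)))
    if plan.k > len(unique):
        raise ValueError(f"k={plan.k} exceeds number of substrates {len(unique)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique))
    folds = []
    for part in np.array_split(perm, plan.k):
        held = set(unique[part])
        test = np.flatnonzero(np.isin(substrates, sorted(held)))
        train = np.flatnonzero(~np.isin(substrates, sorted(held)))
        folds.append((train, test))
    return folds


def train_val_split(indices: np.ndarray, val_fraction: float = 0.15, seed: int = 0):
    """Carve an early-stopping validation subset out of training indices."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(np.asarray(indices))
    n_val = max(1, int(round(val_fraction * len(idx))))
    return np.sort(idx[n_val:]), np.sort(idx[:n_val])


# ------------------------------------------------------------------ training


def _pick_graphs(items, rng: np.random.Generator | None) -> list[MolGraph]:
    if rng is None:
        return [it.graphs[0] for it in items]
    return [it.graphs[int(rng.integers(len(it.graphs)))] for it in items]


def _forward_items(model, items, graphs) -> Tensor:
    if model.config.architecture == "ECFP4NN":
        return model(
            np.stack([it.fingerprint for it in items]),
            np.stack([it.ligand_onehot for it in items]),
            np.stack([it.solvent_onehot for it in items]),
        )
    batch = GraphBatch.from_graphs(graphs)
    if model.config.architecture == "aGNN":
        return model.forward_atomistic(batch)
    cond = np.stack([it.condition for it in items])
    return model.forward_reaction(batch, cond)


def _loss_and_targets(model, items, graphs, loss_kind: str):
    out = _forward_items(model, items, graphs)
    if model.config.architecture == "aGNN":
        y = np.concatenate([it.labels for it in items])[:, None]
        mask = np.concatenate([it.candidate_mask for it in items])[:, None]
        w = Tensor(mask.astype(float) / max(mask.sum(), 1))
        if loss_kind == "bce":
            eps = 1e-7
            clipped = out * (1 - 2 * eps) + eps
            nll = -(Tensor(y) * clipped.log() + Tensor(1.0 - y) * (1.0 - clipped).log())
            return (w * nll).sum()
        return (w * (out - y).square()).sum()
    y = np.array([[it.target] for it in items])
    if loss_kind == "bce":
        eps = 1e-7
        clipped = out * (1 - 2 * eps) + eps
        nll = -(Tensor(y) * clipped.log() + Tensor(1.0 - y) * (1.0 - clipped).log())
        return nll.mean()
    return (out - y).square().mean()


def _validation_mae(model, items) -> float:
    """MAE on the training scale, first conformer (fast per-epoch metric)."""
    preds, targets = [], []
    for i in range(0, len(items), 64):
        chunk = items[i : i + 64]
        out = _forward_items(model, chunk, _pick_graphs(chunk, None))
        if model.config.architecture == "aGNN":
            mask = np.concatenate([it.candidate_mask for it in chunk])
            y = np.concatenate([it.labels for it in chunk])
            preds.append(out.data.ravel()[mask])
            targets.append(y[mask])
        else:
            preds.append(out.data.ravel())
            targets.append(np.array([it.target for it in chunk]))
    p, t = np.concatenate(preds), np.concatenate(targets)
    return float(np.mean(np.abs(p - t)))


def train(
    model: BorylationNet,
    train_items,
    val_items,
    cfg: TrainConfig,
    verbose: bool = False,
) -> dict:
    """Fit the model; returns {'history': [...], 'best_epoch': int}.

    The model is left loaded with the checkpoint minimizing the smoothed
    validation MAE.  Aborts on non-finite loss.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = []
    best = {"smoothed": np.inf, "epoch": -1, "state": model.state_dict()}
    smoothed = None
    randomize_conformer = model.config.is_3d
    for epoch in range(1, cfg.max_epochs + 1):
        opt.lr = cfg.learning_rate * cfg.lr_decay_factor ** ((epoch - 1) // cfg.lr_decay_epochs)
        order = rng.permutation(len(train_items))
        epoch_loss = 0.0
        for i in range(0, len(order), cfg.batch_size):
            chunk = [train_items[j] for j in order[i : i + cfg.batch_size]]
            graphs = _pick_graphs(chunk, rng if randomize_conformer else None)
            loss = _loss_and_targets(model, chunk, graphs, cfg.loss)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(chunk)
        epoch_loss /= len(train_items)
        val_mae = _validation_mae(model, val_items)
        smoothed = (
            val_mae
            if smoothed is None
            else cfg.smoothing_factor * smoothed + (1 - cfg.smoothing_factor) * val_mae
        )
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss, "val_mae": val_mae,
             "smoothed_val_mae": smoothed, "lr": opt.lr}
        )
        if smoothed < best["smoothed"]:
            best = {"smoothed": smoothed, "epoch": epoch, "state": model.state_dict()}
        if verbose:
            print(f"epoch {epoch:4d}  loss {epoch_loss:.5f}  val_mae {val_mae:.5f}")
    model.load_state_dict(best["state"])
    return {"history": history, "best_epoch": best["epoch"]}


# ----------------------------------------------------------------- inference


def predict(model: BorylationNet, items, conformer_index: int = 0) -> np.ndarray:
    """Single-conformer predictions (training scale)."""
    preds = []
    for i in range(0, len(items), 64):
        chunk = items[i : i + 64]
        graphs = [it.graphs[min(conformer_index, len(it.graphs) - 1)] for it in chunk]
        preds.append(_forward_items(model, chunk, graphs).data.ravel())
    return np.concatenate(preds)


def predict_ensemble_batch(model: BorylationNet, items):
    """Vectorized conformer-ensemble prediction over many items.

    Returns (means, stds) over the conformer axis; output length is the
    number of items (molecule-level tasks) or total atoms (aGNN).
    """
    n_conf = max(len(it.graphs) for it in items)
    per_conf = np.stack([predict(model, items, conformer_index=c) for c in range(n_conf)])
    mean = per_conf.mean(axis=0)
    std = per_conf.std(axis=0) if model.config.is_3d else np.zeros_like(mean)
    return mean, std


def predict_ensemble(model: BorylationNet, item, expected_n: int | None = None):
    """Conformer-ensemble prediction: (mean, population std) per output.

    2D variants carry a single conformer-independent graph, so the std is
    exactly zero.  When `expected_n` is given, a conformer count mismatch
    for 3D variants raises.
    """
    if expected_n is not None and model.config.is_3d and len(item.graphs) != expected_n:
        raise ValueError(
            f"conformer count {len(item.graphs)} does not match configured {expected_n}"
        )
    outs = []
    for g in item.graphs:
        outs.append(_forward_items(model, [item], [g]).data.ravel())
    arr = np.stack(outs)  # (n_conformers, n_outputs)
    mean, std = arr.mean(axis=0), arr.std(axis=0)  # population std
    if not model.config.is_3d:
        std = np.zeros_like(mean)
    if mean.size == 1:
        return float(mean[0]), float(std[0])
    return mean, std


# ------------------------------------------------------------------- metrics


@dataclass
class MetricsReport:
    """Binary classification metrics; rates in percent, None when undefined."""

    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float | None = field(init=False)
    tpr: float | None = field(init=False)
    tnr: float | None = field(init=False)
    f_score: float | None = field(init=False)
    balanced_accuracy: float | None = field(init=False)
    accuracy: float | None = field(init=False)

    def __post_init__(self):
        if self.tp + self.fp + self.tn + self.fn != self.n:
            raise ValueError("confusion counts must sum to n")
        self.ppv = 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else None
        self.tpr = 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else None
        self.tnr = 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else None
        self.f_score = (
            fscore_from_rates(self.ppv, self.tpr)
            if self.ppv is not None and self.tpr is not None and self.ppv + self.tpr > 0
            else None
        )
        self.balanced_accuracy = (
            (self.tpr + self.tnr) / 2.0
            if self.tpr is not None and self.tnr is not None
            else None
        )
        self.accuracy = 100.0 * (self.tp + self.tn) / self.n if self.n else None

    def as_dict(self) -> dict:
        return {
            "n": self.n, "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "ppv": self.ppv, "tpr": self.tpr, "tnr": self.tnr, "f_score": self.f_score,
            "balanced_accuracy": self.balanced_accuracy, "accuracy": self.accuracy,
        }


def fscore_from_rates(ppv_percent: float, tpr_percent: float) -> float:
    """F-score as the harmonic mean of PPV and TPR (both in percent)."""
    if ppv_percent + tpr_percent == 0:
        return 0.0
    return 2.0 * ppv_percent * tpr_percent / (ppv_percent + tpr_percent)


def metric_regression(pred, true) -> tuple[float | None, float]:
    """(Pearson r, MAE) on whatever scale the inputs carry (here: percent)."""
    pred, true = np.asarray(pred, float), np.asarray(true, float)
    if pred.size < 2:
        raise ValueError("regression metrics need at least two points")
    mae = float(np.mean(np.abs(pred - true)))
    if np.std(pred) == 0 or np.std(true) == 0:
        return None, mae
    r = float(stats.pearsonr(pred, true).statistic)
    return r, mae


def metric_classification(pred_labels, true_labels) -> MetricsReport:
    pred = np.asarray(pred_labels).astype(bool)
    true = np.asarray(true_labels).astype(bool)
    if pred.shape != true.shape:
        raise ValueError("label arrays must have identical shapes")
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    tn = int(np.sum(~pred & ~true))
    fn = int(np.sum(~pred & true))
    return MetricsReport(n=pred.size, tp=tp, fp=fp, tn=tn, fn=fn)


def roc_auc(scores, true_labels) -> float | None:
    """True ROC-AUC (in percent), reported alongside balanced accuracy."""
    true = np.asarray(true_labels).astype(int)
    if len(set(true.tolist())) < 2:
        return None
    return 100.0 * float(roc_auc_score(true, np.asarray(scores, float)))


# -------------------------------------------------- composite evaluation ops


def evaluate_thresholds(
    records,
    model_factory,
    cfg_train: TrainConfig,
    vocab,
    model_cfg: ModelConfig,
    thresholds=(1, 5, 10, 20),
    n_conformers: int = 10,
    val_fraction: float = 0.15,
    test_fraction: float = 0.25,
) -> dict:
    """Train and evaluate one binary model per conversion threshold.

    Returns {threshold: MetricsReport-dict + auc}.  Thresholds leaving a
    single class are skipped with a warning.
    """
    results = {}
    for th in thresholds:
        labels = [binarize_outcome(r.yield_percent, th) for r in records]
        usable = [i for i, lab in enumerate(labels) if lab is not None]
        classes = {labels[i] for i in usable}
        if len(classes) < 2:
            warnings.warn(f"threshold {th}%: fewer than two outcome classes; skipped")
            continue
        recs = [records[i] for i in usable]
        items = featurize_reactions(recs, model_cfg, vocab, threshold=th,
                                    n_conformers=n_conformers, seed=cfg_train.seed)
        rng = np.random.default_rng(cfg_train.seed)
        perm = rng.permutation(len(items))
        n_test = max(1, int(round(test_fraction * len(items))))
        test_idx, rest = perm[:n_test], perm[n_test:]
        tr_idx, val_idx = train_val_split(rest, val_fraction, cfg_train.seed)
        model = model_factory()
        train(model, [items[i] for i in tr_idx], [items[i] for i in val_idx], cfg_train)
        test_items = [items[i] for i in test_idx]
        scores = predict(model, test_items)
        true = np.array([it.target for it in test_items]) > 0.5
        report = metric_classification(scores > 0.5, true).as_dict()
        report["threshold"] = th
        report["auc"] = roc_auc(scores, true)
        results[th] = report
    return results


def run_repeats(run_fn, seeds=(0, 1, 2)) -> dict:
    """Aggregate metric dicts over independent runs: {metric: (mean, std)}.

    `run_fn(seed)` must return a flat dict of numeric metrics.  The std is
    the sample standard deviation (ddof=1) across runs.
    """
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    runs = [run_fn(s) for s in seeds]
    keys = runs[0].keys()
    out = {}
    for k in keys:
        vals = np.array([r[k] for r in runs], dtype=float)
        out[k] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return out
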