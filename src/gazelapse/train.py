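"""Training protocol, cross-validation and the method comparison benchmark.

All methods are trained under the same protocol: Adam (lr 1e-4, default
moment decays), He initialization, batch size 64, fixed epoch count, and
5-fold cross-validation in which min-max normalization is re-fitted on each
fold's training split only. When each sequence's recording is known, folds
are formed from whole recordings: overlapping sequences share most of their
windows, so shuffling them across folds would leak training rows into
validation. The logistic-regression baseline sees the per-sequence mean of
the same 44 features, so every method receives identical information and
sample counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from gazelapse import features as feats
from gazelapse import nn
from gazelapse.model import (
    DualBranchModel,
    HybridConfig,
    MODEL_CLASSES,
    build_model,
    softmax_cross_entropy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "FoldResult",
    "MethodResult",
    "ComparisonReport",
    "make_folds",
    "make_group_folds",
    "adam_train",
    "evaluate_accuracy",
    "five_fold_cv",
    "train_logistic_baseline",
    "run_methods",
    "comparison_report",
    "make_benchmark_dataset",
]

METHODS = ("hybrid", "conv_only", "recurrent_only", "logistic")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 64
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    folds: int = 5
    class_weights: bool = False

    def validate(self) -> None:
        if min(self.learning_rate, self.epochs, self.batch_size) <= 0:
            raise ValueError("learning_rate, epochs, batch_size must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class FoldResult:
    fold: int
    loss_trace: list[float]
    val_accuracy: float
    n_train: int
    n_val: int


@dataclass
class MethodResult:
    name: str
    fold_accuracies: list[float]
    seed: int
    fold_checksum: str

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))


@dataclass
class ComparisonReport:
    entries: list[MethodResult]

    def sorted_entries(self) -> list[MethodResult]:
        return sorted(self.entries, key=lambda e: e.mean_accuracy, reverse=True)

    def to_dict(self) -> dict:
        return {
            "entries": [
                {
                    "name": e.name,
                    "fold_accuracies": list(map(float, e.fold_accuracies)),
                    "mean_accuracy": e.mean_accuracy,
                    "std_accuracy": e.std_accuracy,
                    "seed": e.seed,
                    "fold_checksum": e.fold_checksum,
                }
                for e in self.sorted_entries()
            ]
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        data = json.loads(text)
        return cls(entries=[
            MethodResult(
                name=e["name"],
                fold_accuracies=e["fold_accuracies"],
                seed=e["seed"],
                fold_checksum=e["fold_checksum"],
            )
            for e in data["entries"]
        ])

    def to_table(self) -> str:
        lines = [f"{'method':<16} {'mean acc':>9} {'sd':>7}  per-fold"]
        best = self.sorted_entries()[0].mean_accuracy if self.entries else 0.0
        for e in self.sorted_entries():
            per = " ".join(f"{a:.3f}" for a in e.fold_accuracies)
            diff = best - e.mean_accuracy
            lines.append(
                f"{e.name:<16} {e.mean_accuracy:>9.3f} {e.std_accuracy:>7.3f}  "
                f"[{per}] (-{diff:.3f} vs best, seed {e.seed})"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# folds

def make_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Shuffle once under the seed, then partition into consecutive folds."""
    if n < folds:
        raise ValueError(f"need at least {folds} sequences, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def make_group_folds(groups: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Folds that never split one group (recording) across train and val.

    Sequences assembled at stride 1 overlap heavily within a recording;
    shuffling them across folds puts near-duplicates of training rows into
    validation and inflates every method's accuracy. Assigning whole
    recordings to folds removes that leakage.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < folds:
        raise ValueError(
            f"grouped {folds}-fold CV needs at least {folds} recordings, "
            f"got {uniq.size}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    parts = np.array_split(perm, folds)
    return [np.sort(np.flatnonzero(np.isin(groups, part))) for part in parts]


def _fold_checksum(fold_indices: list[np.ndarray]) -> str:
    h = hashlib.sha1()
    for part in fold_indices:
        h.update(np.asarray(part, dtype=np.int64).tobytes())
    return h.hexdigest()[:12]


def _split_branches(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (X[:, :, : feats.N_TIME_RELATED],
            X[:, :, feats.N_TIME_RELATED:])


def _method_seed(base_seed: int, fold: int, method: str) -> int:
    ss = np.random.SeedSequence([base_seed, fold, METHODS.index(method)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# training and evaluation

def adam_train(
    model: DualBranchModel,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
) -> list[float]:
    """Train in place with minibatch Adam; returns the per-epoch mean loss.

    Iteration order is reshuffled every epoch under cfg.seed. Minibatches of
    size 1 are skipped (training-mode batch normalization needs two rows).
    """
    cfg.validate()
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    tc, tic = _split_branches(X)
    weights = None
    if cfg.class_weights:
        counts = np.bincount(y, minlength=2).astype(float)
        weights = np.where(counts > 0, n / (2.0 * np.clip(counts, 1, None)), 0.0)
    opt = nn.Adam(model.layers(), lr=cfg.learning_rate, beta1=cfg.beta1,
                  beta2=cfg.beta2, eps=cfg.adam_eps)
    rng = np.random.default_rng(cfg.seed)
    trace: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            if idx.size < 2:
                continue
            opt.zero_grads()
            logits = model.forward(tc[idx], tic[idx], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx], weights)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)) if losses else float("nan"))
    return trace


def evaluate_accuracy(model: DualBranchModel, X: np.ndarray,
                      y: np.ndarray, chunk: int = 512) -> float:
    """Fraction of sequences whose predicted class matches the label.

    A tied probability pair (exactly 0.5/0.5) counts as the negative
    (normal) class and is logged.
    """
    if X.shape[0] == 0:
        raise ValueError("empty evaluation set")
    tc, tic = _split_branches(X)
    preds = np.empty(X.shape[0], dtype=int)
    for lo in range(0, X.shape[0], chunk):
        sl = slice(lo, lo + chunk)
        p = model.predict_proba(tc[sl], tic[sl])
        ties = p[:, 1] == 0.5
        if ties.any():
            logger.info("%d tied predictions broken toward 'normal'",
                        int(ties.sum()))
        preds[sl] = (p[:, 1] > 0.5).astype(int)
    return float(np.mean(preds == np.asarray(y)))


def five_fold_cv(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    method: str = "hybrid",
    model_cfg: HybridConfig | None = None,
    fold_indices: list[np.ndarray] | None = None,
) -> tuple[list[FoldResult], MethodResult]:
    """Shuffled k-fold cross-validation of one neural method.

    Per fold: min-max normalization is fitted on the training windows only,
    the model is freshly initialized, trained for cfg.epochs and scored on
    the held-out fold. The method's accuracy is the mean over folds.
    """
    cfg.validate()
    if fold_indices is None:
        fold_indices = make_folds(X.shape[0], cfg.folds, cfg.seed)
    checksum = _fold_checksum(fold_indices)
    results: list[FoldResult] = []
    for k, val_idx in enumerate(fold_indices):
        train_mask = np.ones(X.shape[0], dtype=bool)
        train_mask[val_idx] = False
        train_idx = np.flatnonzero(train_mask)
        params = feats.fit_minmax(X[train_idx].reshape(-1, X.shape[2]))
        Xtr = apply_norm(X[train_idx], params)
        Xva = apply_norm(X[val_idx], params)
        model = build_model(method, model_cfg,
                            seed=_method_seed(cfg.seed, k, method))
        trace = adam_train(model, Xtr, y[train_idx], cfg)
        acc = evaluate_accuracy(model, Xva, y[val_idx])
        results.append(FoldResult(fold=k, loss_trace=trace, val_accuracy=acc,
                                  n_train=train_idx.size, n_val=val_idx.size))
        logger.info("%s fold %d: val accuracy %.3f", method, k, acc)
    entry = MethodResult(
        name=method,
        fold_accuracies=[r.val_accuracy for r in results],
        seed=cfg.seed,
        fold_checksum=checksum,
    )
    return results, entry


def apply_norm(X: np.ndarray, params: feats.MinMaxParams) -> np.ndarray:
    """Min-max normalize a (m, T, 44) sequence array feature-wise."""
    m, T, d = X.shape
    return feats.apply_minmax(X.reshape(-1, d), params).reshape(m, T, d)


def train_logistic_baseline(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    fold_indices: list[np.ndarray] | None = None,
) -> MethodResult:
    """Binary logistic regression on the per-sequence mean of the 44 features.

    Fitted by Newton iterations (iteratively reweighted least squares) to
    tolerance 1e-8 via statsmodels; perfectly separable folds fall back to a
    weakly regularized scikit-learn fit so the fold still yields predictions.
    """
    import statsmodels.api as sm

    cfg.validate()
    if fold_indices is None:
        fold_indices = make_folds(X.shape[0], cfg.folds, cfg.seed)
    accs = []
    for k, val_idx in enumerate(fold_indices):
        train_mask = np.ones(X.shape[0], dtype=bool)
        train_mask[val_idx] = False
        train_idx = np.flatnonzero(train_mask)
        params = feats.fit_minmax(X[train_idx].reshape(-1, X.shape[2]))
        Ftr = apply_norm(X[train_idx], params).mean(axis=1)
        Fva = apply_norm(X[val_idx], params).mean(axis=1)
        # drop constant columns: they carry no information and break Newton
        keep = Ftr.std(axis=0) > 0
        Ftr, Fva = Ftr[:, keep], Fva[:, keep]
        Atr = sm.add_constant(Ftr, has_constant="add")
        Ava = sm.add_constant(Fva, has_constant="add")
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y[train_idx], Atr).fit(
                    method="newton", tol=1e-8, maxiter=200, disp=0)
            if not res.mle_retvals.get("converged", True):
                raise RuntimeError("Newton did not converge")
            p = np.asarray(res.predict(Ava))
        except Exception:  # separation / singular Hessian
            from sklearn.linear_model import LogisticRegression

            logger.info("logistic fold %d: IRLS failed, falling back to "
                        "regularized fit", k)
            clf = LogisticRegression(C=1e6, max_iter=2000)
            clf.fit(Ftr, y[train_idx])
            p = clf.predict_proba(Fva)[:, 1]
        preds = (p > 0.5).astype(int)  # ties -> normal
        accs.append(float(np.mean(preds == y[val_idx])))
        logger.info("logistic fold %d: val accuracy %.3f", k, accs[-1])
    return MethodResult(
        name="logistic",
        fold_accuracies=accs,
        seed=cfg.seed,
        fold_checksum=_fold_checksum(fold_indices),
    )


def run_methods(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    methods: tuple[str, ...] = METHODS,
    model_cfg: HybridConfig | None = None,
    groups: np.ndarray | None = None,
) -> ComparisonReport:
    """Run every requested method on one shared fold assignment.

    When ``groups`` (one recording id per sequence) is given, folds are
    formed from whole recordings so overlapping sequences never straddle the
    train/validation split.
    """
    if groups is not None:
        fold_indices = make_group_folds(groups, cfg.folds, cfg.seed)
    else:
        fold_indices = make_folds(X.shape[0], cfg.folds, cfg.seed)
    entries = []
    for method in methods:
        if method == "logistic":
            entries.append(train_logistic_baseline(X, y, cfg, fold_indices))
        elif method in MODEL_CLASSES:
            _, entry = five_fold_cv(X, y, cfg, method, model_cfg, fold_indices)
            entries.append(entry)
        else:
            raise ValueError(f"unknown method {method!r}")
    return comparison_report(entries)


def comparison_report(entries: list[MethodResult]) -> ComparisonReport:
    """Validate that all entries share one fold assignment and assemble."""
    if len(entries) >= 2:
        checks = {e.fold_checksum for e in entries}
        if len(checks) > 1:
            raise ValueError(
                "entries come from different fold assignments; "
                "the comparison would be invalid"
            )
    return ComparisonReport(entries=list(entries))


# ---------------------------------------------------------------------------
# synthetic benchmark dataset

def make_benchmark_dataset(
    n_recordings: int,
    duration: float,
    seed: int,
    scan_params=None,
    episode_params=None,
    balance: bool = True,
    sequence_length: int = 6,
    min_overlap: float = 0.5,
    return_groups: bool = False,
) -> tuple[np.ndarray, ...]:
    """Generate recordings, run the full feature pipeline, return sequences.

    Sequences never span recording boundaries. With ``balance`` on, the
    majority class is subsampled (seeded) to the minority count so that
    accuracy has chance level 0.5. With ``return_groups`` on, a third array
    gives each sequence's recording index, for grouped cross-validation.
    """
    from gazelapse import io as gio
    from gazelapse import simulate as sim

    scan_params = scan_params or sim.ScanpathParams()
    episode_params = episode_params or sim.ForgettingEpisodeParams()
    fcfg = feats.FeatureConfig(screen_extent=scan_params.screen_extent)
    ss = np.random.SeedSequence(seed)
    rec_seeds = ss.generate_state(n_recordings + 1) % (2**31)
    xs, ys, gs = [], [], []
    for rec_index, s in enumerate(rec_seeds[:-1]):
        rec = sim.simulate_recording(scan_params, episode_params, duration, int(s))
        g = gio.preprocess(rec.to_recording())
        windows = gio.assign_labels(gio.slide_windows(g), g.episodes,
                                    min_overlap=min_overlap)
        F, labels, _ = feats.windows_to_features(windows, fcfg)
        Xr, yr = feats.assemble_sequences(F, labels, length=sequence_length)
        if Xr.shape[0]:
            xs.append(Xr)
            ys.append(yr)
            gs.append(np.full(yr.shape[0], rec_index))
    if not xs:
        raise ValueError("no sequences generated; increase duration")
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    groups = np.concatenate(gs)
    if balance:
        rng = np.random.default_rng(int(rec_seeds[-1]))
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        if pos.size == 0 or neg.size == 0:
            raise ValueError("benchmark needs both classes; got "
                             f"{pos.size} positive / {neg.size} negative")
        m = min(pos.size, neg.size)
        keep = np.sort(np.concatenate([
            rng.choice(pos, m, replace=False) if pos.size > m else pos,
            rng.choice(neg, m, replace=False) if neg.size > m else neg,
        ]))
        X, y, groups = X[keep], y[keep], groups[keep]
    if return_groups:
        return X, y, groups
    return X, y
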