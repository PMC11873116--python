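"""Classification and importance harness: repeated-holdout AUC evaluation.

Three classifier families are supported, each behind the same
fit-then-score surface:

- random forest with the study hyperparameters (1000 trees, 6 candidate
  variables per split, terminal-node minimum size 5) and mean-decrease-
  Gini importance;
- logistic regression with forward stepwise feature selection by AIC;
- the CNN-style head over frozen backbone features of spectrogram images
  (see :mod:`vowelpd.nnet`).

Evaluation repeats a random 70/30 subject-level split (one recording per
subject makes row splits identity-independent), scoring each held-out
part with the rank-statistic (Mann-Whitney) AUC.  Sampling-based Shapley
attribution and a Wilcoxon rank-sum comparison of AUC distributions
complete the harness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
import statsmodels.api as sm

from vowelpd.errors import DegenerateInputError
from vowelpd.nnet import MLPHead, TinyRandomBackbone

N_ITER_DEFAULT = 100
TRAIN_FRAC_DEFAULT = 0.7


@dataclass(frozen=True)
class FeatureDataset:
    """Feature matrix keyed by subject (one row per subject)."""

    X: np.ndarray  # (n, p)
    y: np.ndarray  # 1 = PD, 0 = HC
    subject_ids: tuple[str, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.subject_ids) != len(set(self.subject_ids)):
            raise ValueError("subject_ids must be unique (one row per subject)")
        if len(self.X) != len(self.y) or len(self.X) != len(self.subject_ids):
            raise ValueError("X, y and subject_ids must have equal length")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class ImageDataset:
    """One image per subject per scale, pixel values in [0, 1]."""

    images: np.ndarray  # (n, H, W, 3)
    y: np.ndarray
    subject_ids: tuple[str, ...]
    scale: str = "mel"

    def __post_init__(self) -> None:
        if len(self.subject_ids) != len(set(self.subject_ids)):
            raise ValueError("subject_ids must be unique (one image per subject)")
        if self.images.min() < 0 or self.images.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class ModelSpec:
    """Classifier kind and hyperparameters (defaults = study settings)."""

    kind: str  # "random_forest" | "stepwise_lr" | "cnn_head"
    n_trees: int = 1000
    vars_per_split: int = 6
    min_node: int = 5
    backbone: str = "tiny-random"
    epochs: int = 10
    batch_size: int = 4
    dropout: float = 0.2
    lr: float = 1e-3

    def __post_init__(self) -> None:
        if self.kind not in ("random_forest", "stepwise_lr", "cnn_head"):
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass(frozen=True)
class EvalResult:
    """Per-iteration held-out AUCs from repeated holdout."""

    aucs: np.ndarray
    seeds: tuple[int, ...]
    n_resampled: int = 0

    def summary(self) -> dict[str, float]:
        q1, med, q3 = np.percentile(self.aucs, [25, 50, 75])
        return {
            "mean": float(self.aucs.mean()),
            "median": float(med),
            "iqr": float(q3 - q1),
            "n_iter": len(self.aucs),
        }


@dataclass(frozen=True)
class ImportanceTable:
    """Per-feature importance values (non-negative), with the method tag."""

    values: pd.Series  # index = feature names, descending
    method: str


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic (Mann-Whitney) AUC; ties count one half.

    Equals the probability that a random positive outscores a random
    negative, and is invariant to strictly monotone score transforms.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def fit_random_forest(
    train: FeatureDataset, spec: ModelSpec | None = None, seed: int = 0
) -> tuple[RandomForestClassifier, ImportanceTable]:
    """Fit the study's random forest; returns model + Gini importance.

    When fewer than ``vars_per_split`` features exist, falls back to
    ``ceil(sqrt(p))`` candidate variables per split.
    """
    spec = spec or ModelSpec(kind="random_forest")
    if train.n < 10:
        raise ValueError("need at least 10 training rows")
    if len(np.unique(train.y)) < 2:
        raise ValueError("training labels must contain both classes")
    p = train.X.shape[1]
    max_features = spec.vars_per_split if p >= spec.vars_per_split else max(
        1, int(np.ceil(np.sqrt(p)))
    )
    model = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=max_features,
        min_samples_leaf=spec.min_node,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(train.X, train.y)
    gini = pd.Series(
        model.feature_importances_, index=list(train.feature_names)
    ).sort_values(ascending=False)
    return model, ImportanceTable(values=gini, method="mean_decrease_gini")


class StepwiseLogit:
    """Forward stepwise logistic regression selected by AIC with a 3-fold
    cross-validation guard.

    Features are standardized with training-set statistics; selection
    starts from the intercept-only model.  At each step the candidate
    minimizing the AIC is proposed, and accepted only if it also lowers
    the 3-fold cross-validated log-loss — without the guard, screening
    many candidates admits noise features whose in-sample likelihood gain
    clears the AIC penalty by selection alone.  Perfect separation (or
    any failed maximum-likelihood fit) triggers an L2-penalized fallback
    fit, recorded in ``separation_flagged``.
    """

    def __init__(self) -> None:
        self.selected: list[int] = []
        self.separation_flagged = False

    @staticmethod
    def _aic(X: np.ndarray, y: np.ndarray) -> float | None:
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                    disp=0, maxiter=100, warn_convergence=False
                )
            if not np.all(np.isfinite(res.params)):
                return None
            return float(res.aic)
        except Exception:  # noqa: BLE001 - separation / singular fits
            return None

    @staticmethod
    def _cv_logloss(Z: np.ndarray, y: np.ndarray, cols: list[int]) -> float:
        """Mean held-out log-loss over 3 deterministic stratified folds."""
        from sklearn.model_selection import StratifiedKFold

        losses = []
        for tr, te in StratifiedKFold(n_splits=3).split(Z, y):
            if len(cols) == 0:
                p1 = float(np.clip(y[tr].mean(), 1e-6, 1 - 1e-6))
                prob = np.full(len(te), p1)
            else:
                try:
                    with np.errstate(all="ignore"):
                        res = sm.Logit(
                            y[tr],
                            sm.add_constant(Z[np.ix_(tr, cols)], has_constant="add"),
                        ).fit(disp=0, maxiter=100, warn_convergence=False)
                    if not np.all(np.isfinite(res.params)):
                        return np.inf
                    eta = res.params[0] + Z[np.ix_(te, cols)] @ res.params[1:]
                    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
                except Exception:  # noqa: BLE001
                    return np.inf
            prob = np.clip(prob, 1e-12, 1 - 1e-12)
            losses.append(
                float(-np.mean(y[te] * np.log(prob) + (1 - y[te]) * np.log(1 - prob)))
            )
        return float(np.mean(losses))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StepwiseLogit":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        if len(y) < 12:
            raise ValueError("need at least 12 rows for stepwise selection")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels must contain both classes")
        self.scaler = StandardScaler().fit(X)
        Z = self.scaler.transform(X)
        p = Z.shape[1]
        # intercept-only AIC: 2*1 - 2*loglik of the prevalence model
        p1 = y.mean()
        ll0 = len(y) * (p1 * np.log(p1 + 1e-300) + (1 - p1) * np.log(1 - p1 + 1e-300))
        best_aic = 2.0 - 2.0 * ll0
        best_cv = self._cv_logloss(Z, y, [])
        selected: list[int] = []
        remaining = list(range(p))
        while remaining:
            scores = []
            for j in remaining:
                aic_j = self._aic(Z[:, selected + [j]], y)
                if aic_j is not None:
                    scores.append((aic_j, j))
            if not scores:
                break
            aic_best, j_best = min(scores)
            if aic_best >= best_aic - 1e-9:
                break
            cv_best = self._cv_logloss(Z, y, selected + [j_best])
            if cv_best >= best_cv - 1e-9:
                break
            best_aic, best_cv = aic_best, cv_best
            selected.append(j_best)
            remaining.remove(j_best)
        self.selected = selected

        cols = selected if selected else list(range(min(1, p)))
        self._cols = cols
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(
                    y, sm.add_constant(Z[:, cols], has_constant="add")
                ).fit(disp=0, maxiter=200, warn_convergence=False)
            if not np.all(np.isfinite(res.params)):
                raise ValueError("non-finite coefficients")
            self._params = np.asarray(res.params)
        except Exception:  # noqa: BLE001
            self.separation_flagged = True
            from sklearn.linear_model import LogisticRegression

            lr = LogisticRegression(C=1.0, max_iter=1000).fit(Z[:, cols], y)
            self._params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(np.asarray(X, dtype=np.float64))
        eta = self._params[0] + Z[:, self._cols] @ self._params[1:]
        p1 = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        return np.column_stack([1.0 - p1, p1])


def fit_logistic_stepwise(train: FeatureDataset, seed: int = 0) -> StepwiseLogit:
    """Fit forward stepwise-AIC logistic regression on a feature dataset."""
    del seed  # deterministic given the data; kept for interface symmetry
    return StepwiseLogit().fit(train.X, train.y)


class CNNHeadModel:
    """Frozen backbone + trained MLP head over spectrogram images."""

    def __init__(self, backbone: TinyRandomBackbone, head: MLPHead):
        self.backbone = backbone
        self.head = head

    @property
    def curve(self):
        return self.head.curve

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.head.predict_proba(self.backbone.features(images))


def fit_cnn_head(
    train: ImageDataset,
    spec: ModelSpec | None = None,
    seed: int = 0,
    val: ImageDataset | None = None,
    backbone: TinyRandomBackbone | None = None,
) -> CNNHeadModel:
    """Train only the MLP classifier head over frozen backbone features."""
    spec = spec or ModelSpec(kind="cnn_head")
    if len(np.unique(train.y)) < 2:
        raise ValueError("training labels must contain both classes")
    backbone = backbone or TinyRandomBackbone(seed=0)
    head = MLPHead(
        dropout=spec.dropout,
        lr=spec.lr,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        seed=seed,
    )
    Xtr = backbone.features(train.images)
    if val is not None:
        head.fit(Xtr, train.y, backbone.features(val.images), val.y)
    else:
        head.fit(Xtr, train.y)
    return CNNHeadModel(backbone, head)


def _subject_split(
    n: int, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def repeated_holdout(
    ds: FeatureDataset | ImageDataset,
    spec: ModelSpec,
    n_iter: int = N_ITER_DEFAULT,
    train_frac: float = TRAIN_FRAC_DEFAULT,
    seed: int = 0,
) -> EvalResult:
    """Repeat random subject-level 70/30 splits; AUC on each held-out part.

    Splits with a class absent from either side are resampled (counted in
    ``n_resampled``).  Deterministic given ``seed``.  For the CNN head the
    frozen backbone features are computed once and shared by iterations.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_iter)
    precomputed = None
    if spec.kind == "cnn_head":
        backbone = TinyRandomBackbone(seed=0)
        precomputed = backbone.features(ds.images)

    aucs = np.zeros(n_iter)
    seeds = []
    n_resampled = 0
    for i in range(n_iter):
        rng = np.random.default_rng(children[i])
        iter_seed = int(children[i].generate_state(1)[0] % (2**31))
        seeds.append(iter_seed)
        for _attempt in range(100):
            tr, te = _subject_split(ds.n, train_frac, rng)
            if len(np.unique(ds.y[tr])) == 2 and len(np.unique(ds.y[te])) == 2:
                break
            n_resampled += 1
        else:
            raise DegenerateInputError("could not draw a two-class split")

        if spec.kind == "random_forest":
            model, _ = fit_random_forest(
                FeatureDataset(
                    ds.X[tr],
                    ds.y[tr],
                    tuple(ds.subject_ids[j] for j in tr),
                    ds.feature_names,
                ),
                spec,
                seed=iter_seed,
            )
            scores = model.predict_proba(ds.X[te])[:, 1]
        elif spec.kind == "stepwise_lr":
            model = StepwiseLogit().fit(ds.X[tr], ds.y[tr])
            scores = model.predict_proba(ds.X[te])[:, 1]
        else:  # cnn_head
            head = MLPHead(
                dropout=spec.dropout,
                lr=spec.lr,
                epochs=spec.epochs,
                batch_size=spec.batch_size,
                seed=iter_seed,
            )
            head.fit(precomputed[tr], ds.y[tr])
            scores = head.predict_proba(precomputed[te])[:, 1]
        aucs[i] = auc(scores, ds.y[te])
    return EvalResult(aucs=aucs, seeds=tuple(seeds), n_resampled=n_resampled)


def shap_importance(
    model,
    X: np.ndarray,
    feature_names: tuple[str, ...],
    n_samples: int = 100,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> ImportanceTable:
    """Monte-Carlo permutation-sampling Shapley attribution.

    For each observation, each of ``n_samples`` draws picks a random
    feature permutation and a random background row, then walks the
    permutation switching features from background to observation values;
    each feature's marginal change in the positive-class probability is
    its contribution for that draw.  The table reports the mean absolute
    attribution per feature across observations (draw sums telescope to
    f(x) - f(background), the efficiency property).
    """
    if n_samples < 10:
        raise ValueError("n_samples must be at least 10")
    X = np.asarray(X, dtype=np.float64)
    bg = X if background is None else np.asarray(background, dtype=np.float64)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    phi_abs = np.zeros(p)
    for i in range(n):
        x = X[i]
        contrib = np.zeros(p)
        # build all intermediate rows for all draws, one predict call
        rows = np.empty((n_samples * (p + 1), p))
        orders = np.empty((n_samples, p), dtype=int)
        for s in range(n_samples):
            order = rng.permutation(p)
            orders[s] = order
            z = bg[rng.integers(len(bg))].copy()
            base = s * (p + 1)
            rows[base] = z
            cur = z.copy()
            for step, j in enumerate(order):
                cur[j] = x[j]
                rows[base + step + 1] = cur
        preds = model.predict_proba(rows)[:, 1].reshape(n_samples, p + 1)
        deltas = np.diff(preds, axis=1)  # (n_samples, p) in permutation order
        for s in range(n_samples):
            contrib[orders[s]] += deltas[s]
        phi_abs += np.abs(contrib / n_samples)
    values = pd.Series(phi_abs / n, index=list(feature_names)).sort_values(
        ascending=False
    )
    return ImportanceTable(values=values, method="mean_abs_shap")


def compare_auc_distributions(
    a: EvalResult | np.ndarray, b: EvalResult | np.ndarray, paired: bool = False
) -> tuple[float, float]:
    """Two-sided Wilcoxon comparison of two AUC samples.

    Default is the unpaired rank-sum (Mann-Whitney) test, exact for small
    samples without ties and normal-approximated with tie correction
    otherwise; ``paired=True`` uses the signed-rank test on per-iteration
    differences.  Returns ``(statistic, p_value)``.
    """
    xa = a.aucs if isinstance(a, EvalResult) else np.asarray(a, dtype=np.float64)
    xb = b.aucs if isinstance(b, EvalResult) else np.asarray(b, dtype=np.float64)
    if len(xa) == 0 or len(xb) == 0:
        raise DegenerateInputError("both AUC samples must be non-empty")
    if paired:
        if len(xa) != len(xb):
            raise ValueError("paired comparison needs equal-length samples")
        if np.allclose(xa, xb):
            return 0.0, 1.0
        res = stats.wilcoxon(xa, xb)
    else:
        if np.array_equal(np.sort(xa), np.sort(xb)) and np.all(xa == xa[0]):
            return 0.0, 1.0
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
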