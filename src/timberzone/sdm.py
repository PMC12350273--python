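"""Habitat suitability models (statsmodels-style Model / Results pairs).

Two complementary learners are fitted to the same climate predictors:

* :class:`RandomForestSDM` — a 500-tree randomized ensemble on labelled
  presence / pseudo-absence rows, with out-of-bag error and permutation
  (mean-decrease-accuracy) importance.
* :class:`MaxEntSDM` — a presence-background maximum-entropy model of the
  exponential family, P(x) ∝ exp(λ·f(x)), fitted through its penalized
  logistic equivalence: an L1-regularized presence-vs-background classifier
  on an expanded feature set (linear, quadratic, pairwise product and hinge
  features), with the penalty scaled by a regularization multiplier.
  The optimiser is an accelerated proximal-gradient (FISTA) loop on the
  exact objective exposed as :func:`penalized_nll`, so fits can be checked
  against brute-force likelihood scans.

Both ``fit()`` methods return Results objects carrying estimates,
diagnostics, ``predict`` / ``predict_surface`` and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .evaluation import EvalMetrics, auc, confusion_metrics, kfold_cv, max_tss_threshold
from .grids import ClimateGrid, SuitabilitySurface


class MissingVariableError(KeyError):
    """A grid or table lacks a variable the fitted model requires."""


def _grid_table(grid: ClimateGrid, feature_names) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    for name in feature_names:
        if name not in grid.variables:
            raise MissingVariableError(f"grid is missing model variable {name!r}")
    rows, cols = np.nonzero(grid.valid)
    table = pd.DataFrame({c: grid.variables[c][rows, cols] for c in feature_names})
    return table, rows, cols


def _surface_from(grid: ClimateGrid, values_at_cells, rows, cols, tag) -> SuitabilitySurface:
    lattice = np.zeros(grid.shape)
    lattice[rows, cols] = np.clip(values_at_cells, 0.0, 1.0)
    return SuitabilitySurface(
        values=lattice,
        model_tag=tag,
        period_label=grid.period_label,
        scenario_label=grid.scenario_label,
        nodata_mask=grid.nodata_mask.copy(),
        cell_size_km=grid.cell_size_km,
        transform=grid.transform,
    )


def permutation_importance(predict, features: pd.DataFrame, labels, metric,
                           seed: int = 0, repeats: int = 5) -> pd.DataFrame:
    """Mean decrease in ``metric`` under within-column permutation.

    ``predict(frame) -> scores``; ``metric(scores, labels) -> float`` (higher
    is better).  Returns one row per variable with the mean drop and its sd
    over ``repeats`` independent permutations.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    labels = np.asarray(labels)
    base = metric(predict(features), labels)
    rng = np.random.default_rng(seed)
    records = []
    for col in features.columns:
        drops = np.empty(repeats)
        for r in range(repeats):
            shuffled = features.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            drops[r] = base - metric(predict(shuffled), labels)
        records.append((col, drops.mean(), drops.std(ddof=1) if repeats > 1 else 0.0))
    return (pd.DataFrame(records, columns=["variable", "importance", "sd"])
            .set_index("variable"))


# ---------------------------------------------------------------------------
# Random forest


class RandomForestSDM:
    """Randomized-tree ensemble on presence / pseudo-absence labels.

    Parameters
    ----------
    features : DataFrame
        Climate predictor table (rows = occurrence points).
    labels : array-like of {0, 1}
        1 = presence, 0 = pseudo-absence.
    n_trees : int
        Ensemble size (default 500).
    train_fraction : float
        Stratified train share; the remainder is the holdout (default 0.75).
    """

    def __init__(self, features: pd.DataFrame, labels, n_trees: int = 500,
                 train_fraction: float = 0.75, seed: int = 0,
                 importance_repeats: int = 5):
        self.features = features.reset_index(drop=True)
        self.labels = np.asarray(labels)
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        self.n_trees = n_trees
        self.train_fraction = train_fraction
        self.seed = seed
        self.importance_repeats = importance_repeats

    def fit(self) -> "RandomForestSDMResults":
        idx = np.arange(len(self.labels))
        train_idx, test_idx = train_test_split(
            idx, train_size=self.train_fraction, stratify=self.labels,
            random_state=self.seed)
        y_train = self.labels[train_idx]
        if y_train.min() == y_train.max():
            raise ValueError("training rows contain a single class")
        est = RandomForestClassifier(
            n_estimators=self.n_trees, oob_score=True, random_state=self.seed,
            n_jobs=1)
        est.fit(self.features.iloc[train_idx], y_train)
        oob_error = 1.0 - float(est.oob_score_)

        test_scores = est.predict_proba(self.features.iloc[test_idx])[:, 1]
        y_test = self.labels[test_idx]
        thr, _ = max_tss_threshold(test_scores, y_test)
        holdout = confusion_metrics(test_scores, y_test, thr)

        def _predict(frame):
            return est.predict_proba(frame[self.features.columns])[:, 1]

        def _acc(scores, labels):
            return float(((scores >= 0.5).astype(int) == labels).mean())

        importance = permutation_importance(
            _predict, self.features.iloc[test_idx].reset_index(drop=True),
            y_test, _acc, seed=self.seed, repeats=self.importance_repeats)
        return RandomForestSDMResults(
            model=self, estimator=est, oob_error=oob_error,
            holdout=holdout, importance=importance,
            train_idx=train_idx, test_idx=test_idx)


@dataclass
class RandomForestSDMResults:
    """Fitted ensemble with OOB error, holdout metrics and importance."""

    model: RandomForestSDM
    estimator: RandomForestClassifier
    oob_error: float
    holdout: EvalMetrics
    importance: pd.DataFrame
    train_idx: np.ndarray
    test_idx: np.ndarray

    @property
    def feature_names(self):
        return list(self.model.features.columns)

    @property
    def accuracy_pct(self) -> float:
        """Predictive accuracy as the OOB-error complement, percent."""
        return oob_accuracy_pct(100.0 * self.oob_error)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise MissingVariableError(f"feature table missing {missing}")
        return self.estimator.predict_proba(features[self.feature_names])[:, 1]

    def predict_surface(self, grid: ClimateGrid) -> SuitabilitySurface:
        table, rows, cols = _grid_table(grid, self.feature_names)
        return _surface_from(grid, self.predict(table), rows, cols, "RF")

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        head = SimpleTable(
            [["trees", self.model.n_trees],
             ["train fraction", self.model.train_fraction],
             ["OOB error", f"{self.oob_error:.4f}"],
             ["accuracy (OOB complement, %)", f"{self.accuracy_pct:.2f}"],
             ["holdout AUC", f"{self.holdout.auc:.4f}"],
             ["holdout TSS", f"{self.holdout.tss:.4f}"],
             ["threshold (max TSS)", f"{self.holdout.threshold:.4f}"]],
            headers=["Random forest SDM", "value"])
        imp = self.importance.sort_values("importance", ascending=False)
        body = SimpleTable(
            [[v, f"{r.importance:.4f}", f"{r.sd:.4f}"]
             for v, r in imp.iterrows()],
            headers=["variable", "mean decrease accuracy", "sd"])
        return str(head) + "\n" + str(body)


def oob_accuracy_pct(oob_error_pct: float) -> float:
    """Predictive accuracy (%) as the complement of the OOB error rate (%)."""
    return 100.0 - oob_error_pct


# ---------------------------------------------------------------------------
# Presence-background maximum-entropy model


@dataclass
class FeatureExpansion:
    """Maxent-style basis: linear, quadratic, pairwise product, hinge.

    Base variables are min-max scaled to [0, 1] over the background range;
    hinge knots sit at training-data quantiles (``n_hinge_knots`` per
    variable, forward hinges).
    """

    names: list[str]
    lo: np.ndarray
    hi: np.ndarray
    classes: tuple[str, ...]
    knots: dict[str, np.ndarray]
    feature_names: list[str]

    @classmethod
    def build(cls, background: pd.DataFrame, training: pd.DataFrame,
              classes=("linear", "quadratic", "product", "hinge"),
              n_hinge_knots: int = 10) -> "FeatureExpansion":
        names = list(background.columns)
        lo = background.to_numpy(dtype=float).min(axis=0)
        hi = background.to_numpy(dtype=float).max(axis=0)
        hi = np.where(hi > lo, hi, lo + 1.0)  # constant column -> zero feature
        knots: dict[str, np.ndarray] = {}
        if "hinge" in classes:
            scaled = (training[names].to_numpy(dtype=float) - lo) / (hi - lo)
            qs = np.linspace(0.0, 1.0, n_hinge_knots + 2)[1:-1]
            for j, name in enumerate(names):
                knots[name] = np.unique(np.quantile(scaled[:, j], qs))
        feature_names: list[str] = []
        if "linear" in classes:
            feature_names += names
        if "quadratic" in classes:
            feature_names += [f"{n}^2" for n in names]
        if "product" in classes:
            feature_names += [f"{a}*{b}" for i, a in enumerate(names)
                              for b in names[i + 1:]]
        if "hinge" in classes:
            for name in names:
                feature_names += [f"hinge({name},{k:.3f})" for k in knots[name]]
        return cls(names, lo, hi, tuple(classes), knots, feature_names)

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.names if c not in frame.columns]
        if missing:
            raise MissingVariableError(f"feature table missing {missing}")
        x = (frame[self.names].to_numpy(dtype=float) - self.lo) / (self.hi - self.lo)
        blocks = []
        if "linear" in self.classes:
            blocks.append(x)
        if "quadratic" in self.classes:
            blocks.append(x ** 2)
        if "product" in self.classes:
            n = x.shape[1]
            blocks.append(np.column_stack(
                [x[:, i] * x[:, j] for i in range(n) for j in range(i + 1, n)])
                if n > 1 else np.empty((len(x), 0)))
        if "hinge" in self.classes:
            for j, name in enumerate(self.names):
                k = self.knots[name][None, :]
                blocks.append(np.clip((x[:, j:j + 1] - k) / (1.0 - k + 1e-12), 0.0, None))
        return np.column_stack(blocks) if blocks else np.empty((len(x), 0))


def penalized_nll(coefs: np.ndarray, intercept: float, X: np.ndarray,
                  y: np.ndarray, alpha: float) -> float:
    """The exact objective minimised by :meth:`MaxEntSDM.fit`.

    Mean Bernoulli negative log-likelihood of presence (1) vs background (0)
    plus ``alpha * ||coefs||_1``; the intercept is unpenalized.
    """
    eta = intercept + X @ coefs
    # log(1 + exp(eta)) - y*eta, computed stably
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    return float(nll + alpha * np.abs(coefs).sum())


def _fista(X, y, alpha, max_iter=20000, tol=1e-9):
    """Accelerated proximal gradient on the penalized logistic objective.

    Stops when the largest parameter update falls below ``tol`` (the
    objective is flat near the optimum, so a parameter criterion is used).
    """
    n, p = X.shape
    Xb = np.column_stack([np.ones(n), X])
    L = (np.linalg.norm(Xb, 2) ** 2) / (4.0 * n)
    step = 1.0 / L
    w = np.zeros(p + 1)  # w[0] = intercept
    z = w.copy()
    t = 1.0
    for _ in range(max_iter):
        eta = Xb @ z
        grad = Xb.T @ (expit(eta) - y) / n
        w_new = z - step * grad
        w_new[1:] = np.sign(w_new[1:]) * np.maximum(np.abs(w_new[1:]) - step * alpha, 0.0)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = w_new + ((t - 1.0) / t_new) * (w_new - w)
        delta = np.abs(w_new - w).max()
        w, t = w_new, t_new
        if delta < tol:
            break
    return w[0], w[1:]


class MaxEntSDM:
    """Presence-background maximum-entropy model (penalized-logistic form).

    Parameters
    ----------
    presence_features, background_features : DataFrame
        Climate predictors at presence points and background cells.
    feature_classes : subset of {"linear", "quadratic", "product", "hinge"}
        Basis expansion ("standard feature classes" by default).
    regularization_multiplier : float
        Scales the L1 penalty (Maxent convention; default 1.0).
    cv_folds : int
        Stratified folds for the embedded cross-validation (default 10).
    output : {"logistic"}
        Suitability scale; the logistic transform of the linear predictor.
    """

    #: Base penalty before the multiplier: alpha = multiplier * 0.1 / sqrt(m),
    #: m the presence count (penalty weakens as evidence accumulates).
    BASE_PENALTY = 0.1

    def __init__(self, presence_features: pd.DataFrame,
                 background_features: pd.DataFrame,
                 feature_classes=("linear", "quadratic", "product", "hinge"),
                 regularization_multiplier: float = 1.0,
                 n_hinge_knots: int = 10, cv_folds: int = 10, seed: int = 0,
                 contribution_repeats: int = 5, output: str = "logistic"):
        if len(presence_features) < 10:
            raise ValueError("need at least 10 presence rows")
        if background_features.empty:
            raise ValueError("background is empty")
        if cv_folds > len(presence_features):
            raise ValueError("more CV folds than presences")
        self.presence = presence_features.reset_index(drop=True)
        self.background = background_features.reset_index(drop=True)
        self.feature_classes = tuple(feature_classes)
        self.regularization_multiplier = float(regularization_multiplier)
        self.n_hinge_knots = n_hinge_knots
        self.cv_folds = cv_folds
        self.seed = seed
        self.contribution_repeats = contribution_repeats
        self.output = output

    @property
    def alpha(self) -> float:
        return (self.regularization_multiplier * self.BASE_PENALTY
                / np.sqrt(len(self.presence)))

    def _stack(self):
        frame = pd.concat([self.presence, self.background], ignore_index=True)
        y = np.concatenate([np.ones(len(self.presence)),
                            np.zeros(len(self.background))])
        return frame, y

    def fit(self, run_cv: bool = True) -> "MaxEntSDMResults":
        frame, y = self._stack()
        expansion = FeatureExpansion.build(
            self.background, frame, classes=self.feature_classes,
            n_hinge_knots=self.n_hinge_knots)
        X = expansion.transform(frame)
        intercept, coefs = _fista(X, y, self.alpha)
        train_scores = expit(intercept + X @ coefs)
        train_auc = auc(train_scores, y)

        cv_metrics, cv_summary = (None, None)
        if run_cv:
            cv_metrics, cv_summary = self._cross_validate(frame, y)
        contribution = self._contribution(frame, y, expansion, intercept, coefs)
        return MaxEntSDMResults(
            model=self, expansion=expansion, intercept=float(intercept),
            coefs=pd.Series(coefs, index=expansion.feature_names),
            train_auc=train_auc, cv_metrics=cv_metrics, cv_summary=cv_summary,
            contribution=contribution)

    def _cross_validate(self, frame, y):
        def fit_eval(tr, te):
            pres_tr = frame.iloc[tr][y[tr] == 1]
            back_tr = frame.iloc[tr][y[tr] == 0]
            sub = MaxEntSDM(
                pres_tr, back_tr, feature_classes=self.feature_classes,
                regularization_multiplier=self.regularization_multiplier,
                n_hinge_knots=self.n_hinge_knots, cv_folds=2, seed=self.seed)
            res = sub.fit(run_cv=False)
            thr, _ = max_tss_threshold(res.predict(frame.iloc[tr]), y[tr])
            return confusion_metrics(res.predict(frame.iloc[te]), y[te], thr)

        return kfold_cv(frame, y, fit_eval, k=self.cv_folds, seed=self.seed)

    def _contribution(self, frame, y, expansion, intercept, coefs):
        def predict(f):
            return expit(intercept + expansion.transform(f) @ coefs)

        imp = permutation_importance(
            predict, frame, y, lambda s, l: auc(s, l),
            seed=self.seed, repeats=self.contribution_repeats)
        raw = imp["importance"].clip(lower=0.0)
        total = raw.sum()
        if total <= 0:
            pct = pd.Series(100.0 / len(raw), index=raw.index)
        else:
            pct = 100.0 * raw / total
        return pct.rename("contribution_pct")


@dataclass
class MaxEntSDMResults:
    """Fitted presence-background model with CV metrics and contributions."""

    model: MaxEntSDM
    expansion: FeatureExpansion
    intercept: float
    coefs: pd.Series
    train_auc: float
    cv_metrics: list[EvalMetrics] | None
    cv_summary: dict | None
    contribution: pd.Series

    @property
    def feature_names(self):
        return list(self.expansion.names)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = self.expansion.transform(features)
        return expit(self.intercept + X @ self.coefs.to_numpy())

    def predict_surface(self, grid: ClimateGrid) -> SuitabilitySurface:
        table, rows, cols = _grid_table(grid, self.feature_names)
        return _surface_from(grid, self.predict(table), rows, cols, "MaxEnt")

    def cumulative_contribution(self, k: int = 4) -> float:
        """Summed percent contribution of the top-k variables."""
        return top_contribution_sum(self.contribution.sort_values(ascending=False)
                                    .head(k).to_list())

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        rows = [["regularization multiplier",
                 self.model.regularization_multiplier],
                ["feature classes", "+".join(self.model.feature_classes)],
                ["active features",
                 int((self.coefs != 0).sum())],
                ["training AUC", f"{self.train_auc:.4f}"]]
        if self.cv_summary is not None:
            rows.append(["CV AUC (mean ± sd)",
                         f"{self.cv_summary['auc'][0]:.4f} ± "
                         f"{self.cv_summary['auc'][1]:.4f}"])
            rows.append(["CV omission (mean)",
                         f"{self.cv_summary['omission_rate'][0]:.4f}"])
        head = SimpleTable(rows, headers=["MaxEnt SDM", "value"])
        contrib = self.contribution.sort_values(ascending=False)
        body = SimpleTable(
            [[v, f"{c:.1f}"] for v, c in contrib.items()],
            headers=["variable", "contribution (%)"])
        return str(head) + "\n" + str(body)


def top_contribution_sum(contributions) -> float:
    """Cumulative percent contribution of a set of variables."""
    return float(np.sum(contributions))
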