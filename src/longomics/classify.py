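"""Classification of stress-event time points versus healthy baselines.

Sparse (l1-regularised) linear classifiers — logistic regression or a
linear SVM — discriminate event-early/event-late visits from healthy
baselines per ome or on all omes concatenated. Splits are always
subject-disjoint: roughly 70% of time points (by subject) train, 30%
test; the regularisation strength C is chosen by an inner 5-fold
subject-aware search on the training set only, and the whole procedure
is repeated over random splits to yield an ROC band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, VisitMetadata

C_GRID = (0.1, 0.5, 1.0, 2.0, 3.0, 5.0, 10.0)
HSCRP_EXCLUSION = 10.0


def rank_auc(scores, labels) -> float:
    """ROC area as the Mann-Whitney rank statistic (ties get half credit)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def make_split(subjects, labels, train_fraction: float = 0.7, seed: int = 0):
    """Subject-disjoint train/test split, ~train_fraction by time-point count.

    Subjects are shuffled and assigned to the training set until it
    holds the requested share of time points; both classes must appear
    on both sides, otherwise further subject orders are tried and
    finally an error is raised.
    """
    subjects = np.asarray(subjects)
    labels = np.asarray(labels).astype(bool)
    uniq = np.unique(subjects)
    rng = np.random.default_rng(seed)
    n = len(subjects)
    for _attempt in range(200):
        order = rng.permutation(uniq)
        train_subj = []
        count = 0
        for s in order:
            if count >= train_fraction * n:
                break
            train_subj.append(s)
            count += int((subjects == s).sum())
        train_subj = set(train_subj)
        train_mask = np.array([s in train_subj for s in subjects])
        ok = (
            labels[train_mask].any()
            and (~labels[train_mask]).any()
            and labels[~train_mask].any()
            and (~labels[~train_mask]).any()
            and train_mask.any()
            and (~train_mask).any()
        )
        if ok:
            return train_mask
    raise ValueError("impossible split: cannot place both classes on both sides")


def _make_estimator(model: str, C: float):
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import LinearSVC

    if model == "logistic":
        return LogisticRegression(l1_ratio=1, C=C, solver="liblinear", max_iter=2000)
    if model == "svm":
        return LinearSVC(penalty="l1", C=C, dual=False, max_iter=5000)
    raise ValueError("model must be 'logistic' or 'svm'")


def fit_and_select(X, y, subjects, model: str = "logistic", C_grid=C_GRID, n_folds: int = 5):
    """Inner subject-aware selection of C, then fit on the full training set."""
    from sklearn.model_selection import GroupKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    subjects = np.asarray(subjects)
    n_groups = len(np.unique(subjects))
    folds = min(n_folds, n_groups)
    best_C, best_err = None, np.inf
    for C in C_grid:
        errs = []
        gkf = GroupKFold(n_splits=folds)
        for tr, va in gkf.split(X, y, groups=subjects):
            if len(np.unique(y[tr])) < 2:
                continue
            est = _make_estimator(model, C)
            est.fit(X[tr], y[tr])
            errs.append(1.0 - (est.predict(X[va]) == y[va]).mean())
        if errs and np.mean(errs) < best_err:
            best_err, best_C = float(np.mean(errs)), C
    if best_C is None:
        raise ValueError("single-class training folds; cannot select C")
    est = _make_estimator(model, best_C)
    est.fit(X, y)
    return est, best_C


def _decision_scores(est, X):
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


@dataclass
class StressEventClassifier:
    """Discriminate EE/EL event visits from healthy baselines.

    ``matrices`` may be a single :class:`OmicsMatrix` or a dict of them
    (multi-ome: standardized features concatenated; samples missing from
    any ome are dropped). Healthy time points with HS-CRP above 10 are
    excluded when an ``hscrp`` series (per sample) is supplied.
    """

    matrices: dict | OmicsMatrix
    metadata: VisitMetadata
    event_type: str = "infection"
    model: str = "logistic"
    hscrp: pd.Series | None = None
    C_grid: tuple = C_GRID

    def _design(self):
        mats = self.matrices if isinstance(self.matrices, dict) else {"ome": self.matrices}
        bio = self.metadata.biological()
        ed = bio["event_day"]
        is_event = (
            (bio["visit_class"] == self.event_type) & (ed >= 1) & (ed <= 14)
        )  # EE + EL windows
        is_healthy = bio["visit_class"] == "healthy"
        if self.hscrp is not None:
            crp = self.hscrp.reindex(bio["sample_id"]).to_numpy()
            is_healthy &= ~(pd.Series(crp, index=bio.index) > HSCRP_EXCLUSION)
        keep = bio[is_event | is_healthy]
        common = None
        for m in mats.values():
            ids = set(m.sample_ids)
            common = ids if common is None else common & ids
        keep = keep[keep["sample_id"].isin(common)]
        samples = keep["sample_id"].tolist()
        y = (keep["visit_class"] == self.event_type).to_numpy()
        subj = keep["subject_id"].to_numpy()
        blocks, names = [], []
        for ome, m in mats.items():
            vals = m.data[samples].to_numpy(dtype=float)
            mu = np.nanmean(vals, axis=1, keepdims=True)
            sd = np.nanstd(vals, axis=1, keepdims=True)
            ok = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
            z = (vals[ok] - mu[ok]) / sd[ok]
            z = np.nan_to_num(z)
            blocks.append(z.T)
            names.extend(f"{ome}:{f}" for f in m.feature_ids[ok])
        X = np.hstack(blocks)
        return X, y, subj, names

    def fit(
        self,
        n_repeats: int = 100,
        train_fraction: float = 0.7,
        seed: int = 0,
        permute_labels: bool = False,
    ) -> "ClassifierEval":
        X, y, subj, names = self._design()
        if len(np.unique(subj[y])) < 2 or len(np.unique(subj[~y])) < 2:
            raise ValueError("need >=2 subjects per class")
        rng = np.random.default_rng(seed)
        aucs, accs, cs, coef_mags = [], [], [], []
        rocs = []
        skipped = 0
        for rep in range(n_repeats):
            y_rep = y.copy()
            if permute_labels:
                y_rep = rng.permutation(y)
            try:
                train = make_split(subj, y_rep, train_fraction, seed=int(rng.integers(2**31)))
                est, C = fit_and_select(
                    X[train], y_rep[train], subj[train], self.model, self.C_grid
                )
            except ValueError:
                skipped += 1
                continue
            scores = _decision_scores(est, X[~train])
            y_test = y_rep[~train]
            if y_test.all() or not y_test.any():
                skipped += 1
                continue
            from sklearn.metrics import roc_curve

            fpr, tpr, _ = roc_curve(y_test, scores)
            aucs.append(rank_auc(scores, y_test))
            accs.append(float((est.predict(X[~train]) == y_test.astype(int)).mean()))
            cs.append(C)
            coef_mags.append(np.abs(np.ravel(est.coef_)))
            rocs.append((fpr, tpr))
        return ClassifierEval(
            ome_set=list(self.matrices) if isinstance(self.matrices, dict) else ["ome"],
            model=self.model,
            auc=np.asarray(aucs),
            accuracy=np.asarray(accs),
            selected_C=cs,
            roc_curves=rocs,
            feature_names=names,
            coef_magnitude=np.mean(coef_mags, axis=0) if coef_mags else np.array([]),
            n_skipped=skipped,
        )


@dataclass
class ClassifierEval:
    ome_set: list
    model: str
    auc: np.ndarray
    accuracy: np.ndarray
    selected_C: list
    roc_curves: list
    feature_names: list = field(default_factory=list)
    coef_magnitude: np.ndarray = field(default_factory=lambda: np.array([]))
    n_skipped: int = 0

    def top_features(self, n: int = 10) -> pd.Series:
        s = pd.Series(self.coef_magnitude, index=self.feature_names)
        return s.sort_values(ascending=False).head(n)

    def summary(self) -> str:
        lines = [
            f"Stress-event classifier ({self.model}, l1) on {'+'.join(map(str, self.ome_set))}",
            f"  repeats: {len(self.auc)} (skipped {self.n_skipped})",
        ]
        if len(self.auc):
            lines += [
                f"  ROC area:  mean {self.auc.mean():.3f}  (2.5-97.5%: "
                f"{np.percentile(self.auc, 2.5):.3f}-{np.percentile(self.auc, 97.5):.3f})",
                f"  accuracy:  mean {self.accuracy.mean():.3f}",
            ]
        return "\n".join(lines)
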