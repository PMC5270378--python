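"""Random-Forest classification of eyes from condition-distance features.

Each eye contributes one sample: its 6-component FE vector (pairwise
Euclidean distances between the four conditions' combined shape+amplitude
features at fusion weight w). Eyes are labelled H (healthy), N (patient
age-affected normal) or D (diseased); the two-class scheme merges H and N
into HN versus D.

The evaluation protocol is repeated random splitting: one third of the
eyes held out as test data, a 500-tree forest fitted on the rest, repeated
10 times; reports pool the contingency counts and average the per-class
error rates. The fusion weight is optimized by sweeping a fixed grid
(0, 0.3, 0.5, 1.0, 1.5, 2.0, 3.0, amplitude-only) with split seeds shared
across grid points for paired comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedShuffleSplit

from .distances import FE_COMPONENTS, condition_distances, fe_vector
from .embedding import Dendrogram
from .errors import DataError, ParameterError
from .features import AMPLITUDE_ONLY, combine, compute_fd, shape_vector, standardize_fd0
from .io import CONDITIONS, RecordingSet, analysis_window

__all__ = [
    "DEFAULT_W_GRID",
    "ClassificationReport",
    "SweepResult",
    "build_feature_rows",
    "rf_classify",
    "weight_sweep",
    "feature_importance",
    "proximity_cluster",
]

#: Fusion-weight grid swept during optimization; infinity denotes the
#: amplitude-only mode (standardized FD_0 alone).
DEFAULT_W_GRID: tuple[float, ...] = (0.0, 0.3, 0.5, 1.0, 1.5, 2.0, 3.0, AMPLITUDE_ONLY)


def build_feature_rows(recordings: RecordingSet, w: float = 1.0) -> pd.DataFrame:
    """One FE-feature row per eye at fusion weight ``w``.

    Per eye: analysis window -> Fourier descriptors -> shape vector and
    per-eye standardized FD_0 -> combined feature at ``w`` -> pairwise
    condition distances -> 6-component FE vector. Deterministic.

    Returns a DataFrame with columns ``subject, eye, label, w`` plus the
    six FE components; exactly ``2 * n_subjects`` rows for a complete
    binocular cohort.

    Raises
    ------
    DataError
        If any subject is incomplete (the message lists the missing
        (eye, condition) pairs).
    """
    incomplete = {
        sid: recordings.missing(sid)
        for sid in recordings.subjects
        if not recordings.is_complete(sid)
    }
    if incomplete:
        raise DataError(f"incomplete subjects (missing eye/condition pairs): {incomplete}")

    rows = []
    for sid in recordings.subjects:
        for eye in recordings.eyes_of(sid):
            fds = {
                c: compute_fd(
                    analysis_window(recordings.get(sid, eye, c)), source=(sid, eye, c)
                )
                for c in CONDITIONS
            }
            amp = standardize_fd0(np.array([fds[c].fd0 for c in CONDITIONS]))
            combined = {
                c: combine(shape_vector(fds[c]), amp.fd0_std[i], w)
                for i, c in enumerate(CONDITIONS)
            }
            fe = fe_vector(condition_distances(combined))
            pg = recordings.get(sid, eye, CONDITIONS[0])
            row = {"subject": sid, "eye": eye, "label": pg.label, "w": w}
            row.update(dict(zip(FE_COMPONENTS, fe)))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ClassificationReport:
    """Pooled results of the repeated-split Random-Forest evaluation.

    ``contingency`` holds true-class rows x predicted-class columns of
    pooled test-set counts over all repeats; ``class_error_mean/sd`` are
    the per-class error rates averaged over repeats.
    """

    scheme: str
    classes: list[str]
    contingency: pd.DataFrame
    class_error_mean: pd.Series
    class_error_sd: pd.Series
    overall_error_mean: float
    overall_error_sd: float
    n_trees: int
    test_fraction: float
    repeats: int
    w: float | None = None

    def to_dict(self) -> dict:
        w = self.w
        if w is not None and math.isinf(w):
            w = "amplitude-only"
        return {
            "scheme": self.scheme,
            "classes": self.classes,
            "contingency": self.contingency.to_dict(),
            "class_error_mean": self.class_error_mean.to_dict(),
            "class_error_sd": self.class_error_sd.to_dict(),
            "overall_error_mean": self.overall_error_mean,
            "overall_error_sd": self.overall_error_sd,
            "n_trees": self.n_trees,
            "test_fraction": self.test_fraction,
            "repeats": self.repeats,
            "w": w,
        }


def _scheme_labels(labels: pd.Series, scheme: str) -> pd.Series:
    if labels.isna().any():
        raise DataError("unlabelled eyes present; classification needs H/N/D labels")
    if scheme == "two_class":
        return labels.map({"H": "HN", "N": "HN", "D": "D"})
    if scheme == "three_class":
        return labels.copy()
    raise ParameterError(f"unknown scheme {scheme!r}")


def rf_classify(
    rows: pd.DataFrame,
    scheme: str = "two_class",
    n_trees: int = 500,
    test_fraction: float = 1 / 3,
    repeats: int = 10,
    seed: int = 0,
    tree_sample_size: int | None = 6,
) -> ClassificationReport:
    """Repeated-split Random-Forest evaluation of FE feature rows.

    Per repeat a stratified random third of the eyes is held out, a forest
    of ``n_trees`` is fitted on the remainder (each tree bootstrapping
    ``tree_sample_size`` samples), and the held-out eyes are scored.
    Stratification keeps every class present in each training split (a
    plain random split of two dozen samples can empty a class). Fully
    reproducible from ``seed``.
    """
    feature_cols = [c for c in FE_COMPONENTS if c in rows.columns]
    if len(feature_cols) != len(FE_COMPONENTS):
        raise DataError("rows are missing FE feature columns")
    if len(rows) < 6:
        raise ParameterError("need at least 6 rows")
    y = _scheme_labels(rows["label"], scheme)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ParameterError("need at least 2 classes present")
    x = rows[feature_cols].to_numpy()
    yv = y.to_numpy()

    # extra splits are drawn so that any split with a class-empty training
    # portion can be discarded (with a warning) and replaced
    splitter = StratifiedShuffleSplit(
        n_splits=2 * repeats, test_size=test_fraction, random_state=seed
    )
    contingency = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    per_repeat_err = []
    rng = np.random.default_rng(seed)
    for train, test in splitter.split(x, yv):
        if len(per_repeat_err) == repeats:
            break
        if len(set(yv[train])) < len(classes):
            warnings.warn("a class was absent from a training split; resampling")
            continue
        max_samples = None
        if tree_sample_size is not None:
            max_samples = min(tree_sample_size, len(train))
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_samples=max_samples,
            random_state=int(rng.integers(2**31 - 1)),
        )
        clf.fit(x[train], yv[train])
        pred = clf.predict(x[test])
        errs = {}
        for true, p in zip(yv[test], pred):
            contingency.loc[true, p] += 1
        for c in classes:
            mask = yv[test] == c
            errs[c] = float(np.mean(pred[mask] != c)) if mask.any() else np.nan
        errs["__overall__"] = float(np.mean(pred != yv[test]))
        per_repeat_err.append(errs)

    err = pd.DataFrame(per_repeat_err)
    return ClassificationReport(
        scheme=scheme,
        classes=classes,
        contingency=contingency,
        class_error_mean=err[classes].mean(),
        class_error_sd=err[classes].std(ddof=1).fillna(0.0),
        overall_error_mean=float(err["__overall__"].mean()),
        overall_error_sd=float(err["__overall__"].std(ddof=1)),
        n_trees=n_trees,
        test_fraction=test_fraction,
        repeats=len(per_repeat_err),
        w=float(rows["w"].iloc[0]) if "w" in rows.columns else None,
    )


@dataclass
class SweepResult:
    """Per-weight classification reports over the fusion-weight grid."""

    reports: dict[float, ClassificationReport] = field(default_factory=dict)

    @property
    def best_w(self) -> float:
        """Grid value minimizing the mean overall error (first on ties)."""
        return min(self.reports, key=lambda w: self.reports[w].overall_error_mean)

    def error_curve(self) -> pd.DataFrame:
        recs = [
            {
                "w": w,
                "overall_error_mean": r.overall_error_mean,
                "overall_error_sd": r.overall_error_sd,
            }
            for w, r in self.reports.items()
        ]
        return pd.DataFrame(recs)


def weight_sweep(
    recordings: RecordingSet,
    scheme: str = "two_class",
    grid: tuple[float, ...] = DEFAULT_W_GRID,
    seed: int = 0,
    **rf_kwargs,
) -> SweepResult:
    """Evaluate classification error across the fusion-weight grid.

    The same split seed is used at every grid point, so comparisons across
    w are paired (lower-variance error differences).
    """
    result = SweepResult()
    for w in grid:
        rows = build_feature_rows(recordings, w=w)
        result.reports[w] = rf_classify(rows, scheme=scheme, seed=seed, **rf_kwargs)
    return result


def feature_importance(
    rows: pd.DataFrame,
    scheme: str = "two_class",
    seed: int = 0,
    n_trees: int = 500,
    repeats: int = 5,
    test_fraction: float = 1 / 3,
    n_permutations: int = 5,
) -> pd.DataFrame:
    """Held-out permutation importance of each FE component, in fixed order.

    Per repeat a stratified third of the eyes is held out, a forest is
    fitted on the rest, and each feature is permuted ``n_permutations``
    times on the held-out portion; importances are averaged over repeats.
    Evaluating on held-out eyes (rather than the training set) keeps the
    importances unbiased: a forest that merely memorizes noise scores zero.

    Returns a 6-row DataFrame ``feature, importance_mean, importance_sd``
    in FE component order.
    """
    y = _scheme_labels(rows["label"], scheme)
    if y.nunique() < 2:
        raise ParameterError("need at least 2 classes present")
    x = rows[list(FE_COMPONENTS)].to_numpy()
    yv = y.to_numpy()
    splitter = StratifiedShuffleSplit(
        n_splits=repeats, test_size=test_fraction, random_state=seed
    )
    rng = np.random.default_rng(seed)
    per_repeat = []
    for train, test in splitter.split(x, yv):
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1))
        )
        clf.fit(x[train], yv[train])
        imp = permutation_importance(
            clf, x[test], yv[test],
            n_repeats=n_permutations,
            random_state=int(rng.integers(2**31 - 1)),
        )
        per_repeat.append(imp.importances_mean)
    stacked = np.stack(per_repeat)
    return pd.DataFrame(
        {
            "feature": list(FE_COMPONENTS),
            "importance_mean": stacked.mean(axis=0),
            "importance_sd": stacked.std(axis=0, ddof=1),
        }
    )


def rf_proximity(
    rows: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 500,
    scheme: str = "three_class",
) -> np.ndarray:
    """Random-Forest proximity matrix of eyes.

    A forest is fitted on all rows; the proximity of two eyes is the
    fraction of trees in which they land in the same leaf. Symmetric with
    a unit diagonal.
    """
    y = _scheme_labels(rows["label"], scheme)
    if y.nunique() < 2:
        raise ParameterError("need at least 2 classes present")
    x = rows[list(FE_COMPONENTS)].to_numpy()
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(x, y)
    leaves = clf.apply(x)  # n_samples x n_trees leaf indices
    return (leaves[:, None, :] == leaves[None, :, :]).mean(axis=2)


def proximity_cluster(
    rows: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 500,
    scheme: str = "three_class",
) -> Dendrogram:
    """Ward dendrogram of eyes from Random-Forest proximities.

    Clustering distance is 1 - proximity (zero diagonal); leaves are
    labelled ``subject:eye:label``.
    """
    prox = rf_proximity(rows, seed=seed, n_trees=n_trees, scheme=scheme)
    dist = 1.0 - prox
    np.fill_diagonal(dist, 0.0)
    labels = [
        f"{r.subject}:{r.eye}:{r.label}" for r in rows.itertuples(index=False)
    ]
    z = sch.linkage(squareform(dist, checks=False), method="ward")
    return Dendrogram(linkage_matrix=z, labels=labels)
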