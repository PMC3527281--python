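"""Linear-SVM ensemble over per-tool combined gene scores.

Per-tool combined scores (FD or WSUM) are assembled into a gene x tool
feature matrix, optionally normalized onto the training score distribution
(for cross-dataset / cross-species application), z-scored with training
statistics, and fed to a linear-kernel SVM.  The ensemble's output is a
calibrated class probability in [0, 1]: a Platt-style sigmoid is fitted to
out-of-fold SVM decision values, so higher decision values map monotonically
to higher targeting probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .thermo import GeneScoreTable

MODEL_SCHEMA_VERSION = 1

NORMALIZATION_METHODS = ("rank", "mean", "none")


@dataclass
class NormalizationMap:
    """Maps new score distributions onto a reference (training) distribution.

    ``rank``: a score at empirical quantile q is replaced by the reference
    quantile at q (linear interpolation, average ranks for ties) — strictly
    order-preserving. ``mean``: scores are rescaled so their mean matches the
    reference mean. ``none``: identity.
    """

    method: str
    reference: np.ndarray | float | None = None
    tool: str = ""

    def __post_init__(self) -> None:
        if self.method not in NORMALIZATION_METHODS:
            raise ValueError(f"unknown normalization method {self.method!r}")


def fit_normalization(reference_scores, method: str, tool: str = "") -> NormalizationMap:
    """Fit a normalization map from reference (training) scores."""
    if method == "none":
        return NormalizationMap("none", None, tool)
    ref = np.asarray(reference_scores, dtype=float)
    if ref.size == 0:
        raise ValueError("cannot fit normalization to an empty reference")
    if method == "rank":
        return NormalizationMap("rank", np.sort(ref), tool)
    if method == "mean":
        return NormalizationMap("mean", float(ref.mean()), tool)
    raise ValueError(f"unknown normalization method {method!r}")


def apply_normalization(nmap: NormalizationMap, scores) -> np.ndarray:
    """Apply a fitted map to a score vector."""
    x = np.asarray(scores, dtype=float)
    if nmap.method == "none":
        return x.copy()
    if nmap.reference is None:
        raise ValueError("normalization map has not been fitted")
    if nmap.method == "rank":
        if x.size == 1:
            q = np.array([0.5])
        else:
            ranks = rankdata(x, method="average")
            q = (ranks - 1.0) / (x.size - 1.0)
        return np.quantile(np.asarray(nmap.reference), q)
    # mean
    m = x.mean()
    if m == 0:
        raise ValueError("mean normalization undefined for zero-mean input")
    return x * (float(nmap.reference) / m)


@dataclass
class FeatureMatrix:
    """Dense gene x tool matrix of combined scores (missing entries = 0)."""

    genes: list[str]
    tools: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.genes), len(self.tools)):
            raise ValueError(
                f"feature matrix shape {self.X.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.tools)} tools"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.genes, columns=self.tools)


def build_feature_matrix(tables: Sequence[GeneScoreTable]) -> FeatureMatrix:
    """Assemble per-tool score tables into one feature matrix.

    Rows are the union of genes, columns the tools, both in lexicographic
    order; a gene absent from a tool's table gets 0 (no detected sites).
    """
    if not tables:
        raise ValueError("need at least one score table")
    labels = [t.tool for t in tables]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate tool labels: {sorted(labels)}")
    genes = sorted(set().union(*(t.scores.index for t in tables)))
    tools = sorted(labels)
    by_tool = {t.tool: t.scores for t in tables}
    X = np.zeros((len(genes), len(tools)))
    for j, tool in enumerate(tools):
        X[:, j] = by_tool[tool].reindex(genes, fill_value=0.0).to_numpy()
    return FeatureMatrix(genes, tools, X)


@dataclass
class EnsembleModel:
    """Trained linear SVM + calibration + per-tool normalization maps."""

    tools: list[str]
    coef: np.ndarray            # one weight per tool, on z-scored features
    intercept: float
    feature_mean: np.ndarray    # training standardization
    feature_sd: np.ndarray
    cal_slope: float            # sigmoid on decision values
    cal_intercept: float
    normalization: dict[str, NormalizationMap] = field(default_factory=dict)
    seed: int = 0
    C: float = 1.0
    n_pos: int = 0
    n_neg: int = 0

    def decision_values(self, X: FeatureMatrix) -> np.ndarray:
        Z = self._standardized(X)
        return Z @ self.coef + self.intercept

    def _standardized(self, X: FeatureMatrix) -> np.ndarray:
        missing = [t for t in self.tools if t not in X.tools]
        extra = [t for t in X.tools if t not in self.tools]
        if missing or extra:
            raise ValueError(
                f"feature/model tool mismatch: missing from input {missing}, "
                f"unexpected in input {extra}"
            )
        cols = [X.tools.index(t) for t in self.tools]
        V = X.X[:, cols].copy()
        for j, tool in enumerate(self.tools):
            nmap = self.normalization.get(tool)
            if nmap is not None and nmap.method != "none":
                V[:, j] = apply_normalization(nmap, V[:, j])
        return (V - self.feature_mean) / self.feature_sd

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        norm = {
            tool: {
                "method": m.method,
                "reference": (
                    None if m.reference is None
                    else m.reference if np.isscalar(m.reference)
                    else np.asarray(m.reference).tolist()
                ),
            }
            for tool, m in self.normalization.items()
        }
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "tools": list(self.tools),
            "coef": np.asarray(self.coef).tolist(),
            "intercept": self.intercept,
            "feature_mean": np.asarray(self.feature_mean).tolist(),
            "feature_sd": np.asarray(self.feature_sd).tolist(),
            "calibration": {"slope": self.cal_slope, "intercept": self.cal_intercept},
            "normalization": norm,
            "seed": self.seed,
            "C": self.C,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {d.get('schema_version')}")
        norm = {}
        for tool, m in d.get("normalization", {}).items():
            ref = m["reference"]
            if isinstance(ref, list):
                ref = np.asarray(ref, dtype=float)
            norm[tool] = NormalizationMap(m["method"], ref, tool)
        return cls(
            tools=list(d["tools"]),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            feature_mean=np.asarray(d["feature_mean"], dtype=float),
            feature_sd=np.asarray(d["feature_sd"], dtype=float),
            cal_slope=float(d["calibration"]["slope"]),
            cal_intercept=float(d["calibration"]["intercept"]),
            normalization=norm,
            seed=int(d["seed"]),
            C=float(d["C"]),
            n_pos=int(d["n_pos"]),
            n_neg=int(d["n_neg"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _align_labels(X: FeatureMatrix, labels) -> np.ndarray:
    if isinstance(labels, (pd.Series, Mapping)):
        s = pd.Series(labels)
        missing = [g for g in X.genes if g not in s.index]
        if missing:
            raise ValueError(f"labels missing for {len(missing)} gene(s), e.g. {missing[:5]}")
        y = s.loc[X.genes].to_numpy()
    else:
        y = np.asarray(labels)
        if y.shape[0] != len(X.genes):
            raise ValueError("label vector length does not match gene count")
    y = y.astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    return y


def train_ensemble(
    X: FeatureMatrix,
    labels,
    *,
    seed: int = 0,
    C: float = 1.0,
    normalization: str = "none",
) -> EnsembleModel:
    """Train the linear-SVM ensemble with calibrated probability output.

    ``normalization`` fits a per-tool map (rank/mean/none) from the training
    feature columns; the map is stored in the model and applied to future
    inputs, anchoring new datasets to the training score distribution.
    Deterministic given ``seed`` (internal calibration folds are seeded).
    """
    y = _align_labels(X, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training labels must contain both classes")

    norm_maps = {
        tool: fit_normalization(X.X[:, X.tools.index(tool)], normalization, tool)
        for tool in X.tools
    }
    V = X.X.copy()  # training columns are the normalization reference: identity here
    mean = V.mean(axis=0)
    sd = V.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (V - mean) / sd

    svc = SVC(kernel="linear", C=C, random_state=seed)
    svc.fit(Z, y)
    if list(svc.classes_) != [0, 1]:  # pragma: no cover - sklearn sorts classes
        raise AssertionError("unexpected class order")

    # Platt-style calibration: sigmoid on out-of-fold decision values.
    n_splits = min(5, n_pos, n_neg)
    if n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        d = cross_val_predict(
            SVC(kernel="linear", C=C, random_state=seed), Z, y,
            cv=cv, method="decision_function",
        )
    else:
        d = svc.decision_function(Z)
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=5000)
    lr.fit(d.reshape(-1, 1), y)

    return EnsembleModel(
        tools=list(X.tools),
        coef=svc.coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        feature_mean=mean,
        feature_sd=sd,
        cal_slope=float(lr.coef_[0, 0]),
        cal_intercept=float(lr.intercept_[0]),
        normalization=norm_maps,
        seed=seed,
        C=C,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def predict_probability(model: EnsembleModel, X: FeatureMatrix) -> pd.Series:
    """Per-gene targeting probability in [0, 1], monotone in the SVM decision."""
    d = model.decision_values(X)
    p = expit(model.cal_slope * d + model.cal_intercept)
    return pd.Series(p, index=X.genes, name="probability")


def kfold_auc(
    X: FeatureMatrix,
    labels,
    *,
    seed: int = 0,
    n_splits: int = 5,
    C: float = 1.0,
) -> float:
    """Cross-validated AUC of the linear SVM (decision values, per-fold scaling)."""
    y = _align_labels(X, labels)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    pipe = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C, random_state=seed))
    d = cross_val_predict(pipe, X.X, y, cv=cv, method="decision_function")
    return float(roc_auc_score(y, d))
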