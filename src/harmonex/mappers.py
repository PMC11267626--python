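"""Harmonization mappers behind a single train/predict contract.

Every harmonization method — the two equating methods, the IRT crosswalk
and the six machine-learning methods — is wrapped as a
:class:`HarmonizationModel` so the evaluation loop can iterate one registry
of valid (method, mapping-setting) combinations.

Mapping settings (how the two scales are linked):

* ``sum_to_sum``   — source sum score is the only predictor.  Only
  meaningful for equating and for linear/ordinal regression; with a single
  predictor, random forests and support vector machines degenerate.
* ``items_to_sum`` — the 5 source item responses predict the target sum.
* ``items_to_items`` — one sub-model per target item; predicted item
  responses are summed.  Not offered for IRT, whose crosswalk already
  passes through the item level by construction.

The full valid grid has exactly 17 combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVC, SVR

from . import irt
from .equating import (
    apply_equating,
    kernel_equate_single_group,
    linear_equate,
    score_distribution,
)
from .types import ResponseDataset

__all__ = [
    "SETTINGS",
    "METHODS",
    "REGISTRY",
    "valid_combinations",
    "build_features",
    "make_mapper",
    "train_mapper",
    "predict_mapper",
    "HarmonizationModel",
]

SETTINGS = ("sum_to_sum", "items_to_sum", "items_to_items")

#: methods allowed per setting; the product enumerates the comparison grid
METHODS = {
    "linear_equating": ("sum_to_sum",),
    "kernel_equating": ("sum_to_sum",),
    "irt": ("items_to_sum",),
    "linear_regression": ("sum_to_sum", "items_to_sum", "items_to_items"),
    "ordinal_regression": ("sum_to_sum", "items_to_sum", "items_to_items"),
    "rf_regression": ("items_to_sum", "items_to_items"),
    "rf_classification": ("items_to_sum", "items_to_items"),
    "svm_regression": ("items_to_sum", "items_to_items"),
    "svm_classification": ("items_to_items", "items_to_sum"),
}

REGISTRY: tuple[tuple[str, str], ...] = tuple(
    (method, setting) for method, settings in METHODS.items() for setting in settings
)


def valid_combinations() -> list[tuple[str, str]]:
    """All valid (method, setting) pairs, in registry order (17 in total)."""
    return list(REGISTRY)


def _check_combination(method: str, setting: str) -> None:
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; known: {sorted(METHODS)}")
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}; known: {SETTINGS}")
    if setting not in METHODS[method]:
        if setting == "sum_to_sum":
            reason = (
                "a single sum-score predictor is only sensible for equating "
                "and for linear/ordinal regression"
            )
        else:
            reason = "the IRT crosswalk already operates on items internally"
        raise ValueError(f"({method}, {setting}) is not a valid combination: {reason}")


def build_features(dataset: ResponseDataset, setting: str):
    """Predictor matrix and target(s) for a mapping setting.

    Returns ``(X, y)`` where ``y`` is the target sum vector, except for
    ``items_to_items`` where it is the full target item matrix (one column
    per sub-model).
    """
    if setting == "sum_to_sum":
        return dataset.source_sums.reshape(-1, 1).astype(float), dataset.target_sums
    if setting == "items_to_sum":
        return dataset.source_responses.astype(float), dataset.target_sums
    if setting == "items_to_items":
        return dataset.source_responses.astype(float), dataset.target_responses
    raise ValueError(f"unknown setting {setting!r}; known: {SETTINGS}")


@dataclass
class HarmonizationModel:
    """A fitted mapper tagged by method and mapping setting.

    ``output_type`` is ``"integer"`` for classification-type methods
    (their predictions are category labels) and ``"real"`` otherwise.
    Regression-type sum predictions are clamped to the target sum range.
    """

    method: str
    setting: str
    output_type: str = "real"
    seed: int = 0
    round_items: bool = False
    soft_labels: bool = False
    state: dict = field(default_factory=dict)

    # -- fitting -----------------------------------------------------------
    def fit(self, train: ResponseDataset) -> "HarmonizationModel":
        _check_combination(self.method, self.setting)
        self.state["target_range"] = (
            (0, int(train.target_responses.shape[1] * 2))
            if train.target_scale is None
            else train.target_scale.sum_range
        )
        self.state["n_target_items"] = train.target_responses.shape[1]
        getattr(self, f"_fit_{self.method}")(train)
        return self

    def _fit_linear_equating(self, train: ResponseDataset) -> None:
        src_range = (0, int(train.source_responses.shape[1] * 2))
        src = score_distribution(train.source_sums, src_range)
        tgt = score_distribution(train.target_sums, self.state["target_range"])
        self.state["equating_fn"] = linear_equate(src, tgt)

    def _fit_kernel_equating(self, train: ResponseDataset) -> None:
        src_range = (0, int(train.source_responses.shape[1] * 2))
        self.state["equating_fn"] = kernel_equate_single_group(
            train.source_sums,
            train.target_sums,
            src_range,
            self.state["target_range"],
        )

    def _fit_irt(self, train: ResponseDataset) -> None:
        joint = np.hstack([train.source_responses, train.target_responses])
        ids = [f"src_{j + 1}" for j in range(train.source_responses.shape[1])] + [
            f"tgt_{j + 1}" for j in range(train.target_responses.shape[1])
        ]
        self.state["gpcm_fit"] = irt.fit_gpcm(joint, item_ids=ids)
        self.state["n_source_items"] = train.source_responses.shape[1]
        self.state["train_ref"] = train

    def _fit_linear_regression(self, train: ResponseDataset) -> None:
        X, y = build_features(train, self.setting)
        if self.setting == "items_to_items":
            self.state["models"] = [
                LinearRegression().fit(X, y[:, j]) for j in range(y.shape[1])
            ]
        else:
            self.state["models"] = [LinearRegression().fit(X, y)]

    def _fit_ordinal_regression(self, train: ResponseDataset) -> None:
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        X, y = build_features(train, self.setting)
        targets = y.T if self.setting == "items_to_items" else [y]
        fits = []
        for yj in targets:
            cats = np.unique(yj)
            if cats.size < 2:
                # constant target: degenerate model, predict the constant
                fits.append(("constant", float(cats[0])))
                continue
            model = OrderedModel(yj.astype(float), X, distr="logit")
            res = model.fit(method="bfgs", disp=False, maxiter=500, gtol=1e-6)
            fits.append(("ordinal", (res, cats)))
        self.state["models"] = fits
        self.output_type = "integer" if not self.soft_labels else "real"

    def _fit_forest(self, train: ResponseDataset, classify: bool) -> None:
        X, y = build_features(train, self.setting)
        cls = RandomForestClassifier if classify else RandomForestRegressor
        kw = dict(n_estimators=500, random_state=self.seed, n_jobs=1)
        targets = y.T if self.setting == "items_to_items" else [y]
        self.state["models"] = [cls(**kw).fit(X, yj) for yj in targets]

    def _fit_rf_regression(self, train: ResponseDataset) -> None:
        self._fit_forest(train, classify=False)

    def _fit_rf_classification(self, train: ResponseDataset) -> None:
        # classification forest on the ordered labels; the default prediction
        # is the majority-vote class (hard, nominal treatment).  With
        # soft_labels the aggregation is score-based instead: the expected
        # label under the class probabilities, rounded to the nearest label.
        self._fit_forest(train, classify=True)
        self.output_type = "integer"

    def _fit_svm(self, train: ResponseDataset, classify: bool) -> None:
        X, y = build_features(train, self.setting)
        targets = y.T if self.setting == "items_to_items" else [y]
        models = []
        for yj in targets:
            if classify:
                if np.unique(yj).size < 2:
                    models.append(("constant", float(yj[0])))
                    continue
                m = SVC(kernel="linear", C=1.0, random_state=self.seed).fit(X, yj)
            else:
                m = SVR(kernel="linear", C=1.0, epsilon=0.1).fit(X, yj)
            models.append(("model", m))
        self.state["models"] = models

    def _fit_svm_regression(self, train: ResponseDataset) -> None:
        self._fit_svm(train, classify=False)

    def _fit_svm_classification(self, train: ResponseDataset) -> None:
        self._fit_svm(train, classify=True)
        self.output_type = "integer"

    # -- prediction --------------------------------------------------------
    def predict(self, source_responses: np.ndarray) -> np.ndarray:
        """Predicted target sum scores for test persons (source data only)."""
        source_responses = np.asarray(source_responses)
        pred = getattr(self, f"_predict_{self.method}")(source_responses)
        lo, hi = self.state["target_range"]
        if self.output_type == "real":
            pred = np.clip(pred, lo, hi)
        return pred

    def _features(self, source_responses: np.ndarray) -> np.ndarray:
        if self.setting == "sum_to_sum":
            return source_responses.sum(axis=1).reshape(-1, 1).astype(float)
        return source_responses.astype(float)

    def _predict_linear_equating(self, src: np.ndarray) -> np.ndarray:
        return apply_equating(self.state["equating_fn"], src.sum(axis=1))

    _predict_kernel_equating = _predict_linear_equating

    def _predict_irt(self, src: np.ndarray) -> np.ndarray:
        return irt.irt_harmonize(
            self.state["train_ref"], src, fit=self.state["gpcm_fit"]
        )

    def _predict_linear_regression(self, src: np.ndarray) -> np.ndarray:
        X = self._features(src)
        preds = np.column_stack([m.predict(X) for m in self.state["models"]])
        if self.setting == "items_to_items":
            if self.round_items:
                preds = np.clip(np.rint(preds), 0, 2)
            return preds.sum(axis=1)
        return preds[:, 0]

    def _predict_ordinal_regression(self, src: np.ndarray) -> np.ndarray:
        X = self._features(src)
        cols = []
        for kind, payload in self.state["models"]:
            if kind == "constant":
                cols.append(np.full(X.shape[0], payload))
                continue
            res, cats = payload
            probs = res.model.predict(res.params, exog=X)
            if self.soft_labels:
                cols.append(probs @ cats)
            else:
                cols.append(cats[np.argmax(probs, axis=1)])
        out = np.column_stack(cols)
        return out.sum(axis=1) if self.setting == "items_to_items" else out[:, 0]

    def _predict_rf_regression(self, src: np.ndarray) -> np.ndarray:
        X = self._features(src)
        preds = np.column_stack([m.predict(X) for m in self.state["models"]])
        if self.setting == "items_to_items":
            if self.round_items:
                preds = np.clip(np.rint(preds), 0, 2)
            return preds.sum(axis=1)
        return preds[:, 0]

    def _predict_rf_classification(self, src: np.ndarray) -> np.ndarray:
        X = self._features(src)
        cols = []
        for m in self.state["models"]:
            if self.soft_labels:
                expected = m.predict_proba(X) @ m.classes_.astype(float)
                idx = np.abs(expected[:, None] - m.classes_[None, :]).argmin(axis=1)
                cols.append(m.classes_[idx])
            else:
                cols.append(m.predict(X))
        out = np.column_stack(cols)
        return out.sum(axis=1) if self.setting == "items_to_items" else out[:, 0]

    def _predict_svm_regression(self, src: np.ndarray) -> np.ndarray:
        X = self._features(src)
        preds = np.column_stack([m.predict(X) for _, m in self.state["models"]])
        if self.setting == "items_to_items":
            if self.round_items:
                preds = np.clip(np.rint(preds), 0, 2)
            return preds.sum(axis=1)
        return preds[:, 0]

    def _predict_svm_classification(self, src: np.ndarray) -> np.ndarray:
        X = self._features(src)
        cols = []
        for kind, m in self.state["models"]:
            if kind == "constant":
                cols.append(np.full(X.shape[0], m))
            else:
                cols.append(m.predict(X))
        out = np.column_stack(cols)
        return out.sum(axis=1) if self.setting == "items_to_items" else out[:, 0]


def make_mapper(method: str, setting: str, seed: int = 0, **kwargs) -> HarmonizationModel:
    """Instantiate an unfitted mapper, validating the combination."""
    _check_combination(method, setting)
    return HarmonizationModel(method=method, setting=setting, seed=seed, **kwargs)


def train_mapper(
    method: str, setting: str, train: ResponseDataset, seed: int = 0, **kwargs
) -> HarmonizationModel:
    """Fit a mapper on a training dataset."""
    return make_mapper(method, setting, seed=seed, **kwargs).fit(train)


def predict_mapper(model: HarmonizationModel, source_responses: np.ndarray) -> np.ndarray:
    """Apply a fitted mapper to test-set source responses."""
    return model.predict(source_responses)
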