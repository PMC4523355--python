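"""Proof-of-concept trait-based species identification.

A random-forest ensemble is trained on trajectory summaries from
monocultures (where the species of every trajectory is known) and then used
to predict species identity in mixed cultures from the same traits.  Two
feature sets are compared: morphology summaries only, or morphology plus
movement summaries — movement typically adds discriminatory power for
species that overlap in shape but differ in behaviour.

Classification is deliberately not part of the core pipeline: the trait
tables are classifier-agnostic, and the random forest here is one worked
example.  Class imbalance is surfaced (per-class support is reported) but
not corrected; badly under-represented classes can be absorbed into a
similar majority class, which is a known failure mode of forests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .morphology import MORPHOLOGY_DESCRIPTORS

#: morphology summary features (means/medians/SDs of the descriptor set)
MORPHOLOGY_FEATURES = [
    f"{c}_{s}" for c in MORPHOLOGY_DESCRIPTORS for s in ("mean", "median", "sd")
]
#: movement summary features added by the "morphology+movement" set
MOVEMENT_FEATURES = [
    "net_displacement",
    "gross_displacement",
    "median_step",
    "mean_step",
    "sd_step",
    "mean_speed",
    "mean_turning",
    "sd_turning",
]

FEATURE_SETS = {
    "morphology": MORPHOLOGY_FEATURES,
    "morphology+movement": MORPHOLOGY_FEATURES + MOVEMENT_FEATURES,
}


@dataclass
class ConfusionReport:
    """Out-of-bag confusion matrix and overall classification success.

    ``matrix`` is row-normalised (each true-species row sums to 1);
    ``success`` is 100·(1 − out-of-bag error) in percent; ``support`` is
    the number of training trajectories per class.
    """

    matrix: pd.DataFrame
    success: float
    support: pd.Series

    def __str__(self) -> str:
        lines = [
            f"classification success (1 - OOB error): {self.success:.1f}%",
            "per-class support: "
            + ", ".join(f"{k}={v}" for k, v in self.support.items()),
            self.matrix.round(3).to_string(),
        ]
        return "\n".join(lines)


@dataclass
class SpeciesClassifier:
    """Trained ensemble plus the feature contract it expects."""

    estimator: RandomForestClassifier
    features: list[str]
    feature_set: str
    classes: list[str]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump(self, path)
        return path

    @staticmethod
    def load(path: str | Path) -> "SpeciesClassifier":
        return joblib.load(path)


def _feature_matrix(
    summaries: pd.DataFrame, features: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    missing = [f for f in features if f not in summaries.columns]
    if missing:
        raise ValueError(f"summary table is missing feature columns: {missing}")
    X = summaries[features]
    ok = ~X.isna().any(axis=1)
    return X.loc[ok], list(summaries.index[ok])


def train_classifier(
    summaries: pd.DataFrame,
    label_col: str = "species",
    feature_set: str | list[str] = "morphology",
    seed: int = 0,
    n_estimators: int = 500,
) -> tuple[SpeciesClassifier, ConfusionReport]:
    """Train on labelled trajectory summaries; report out-of-bag confusion.

    ``feature_set`` is ``"morphology"``, ``"morphology+movement"`` or an
    explicit list of summary columns.

    Requires at least two species with at least two trajectories each.
    Rows with missing feature values (e.g. single-detection trajectories
    with undefined SDs) are dropped with a warning.
    """
    if isinstance(feature_set, (list, tuple)):
        candidates = list(feature_set)
        feature_set = "custom"
    elif feature_set in FEATURE_SETS:
        candidates = FEATURE_SETS[feature_set]
    else:
        raise ValueError(
            f"feature_set must be one of {sorted(FEATURE_SETS)} or an explicit "
            f"column list, got {feature_set!r}"
        )
    if label_col not in summaries.columns:
        raise ValueError(f"summary table has no label column {label_col!r}")
    features = [f for f in candidates if f in summaries.columns]
    X, rows = _feature_matrix(summaries, features)
    if len(X) < len(summaries):
        warnings.warn(
            f"dropped {len(summaries) - len(X)} rows with missing feature values",
            stacklevel=2,
        )
    y = summaries.loc[rows, label_col].astype(str)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError(f"need at least 2 species to train, got {classes}")
    support = y.value_counts()
    if (support < 2).any():
        raise ValueError(
            f"need at least 2 trajectories per species, got {support.to_dict()}"
        )
    rf = RandomForestClassifier(
        n_estimators=n_estimators, oob_score=True, random_state=seed
    )
    rf.fit(X.to_numpy(), y.to_numpy())
    oob = rf.oob_decision_function_
    # rows never out of bag have all-NaN votes; count them as errors
    valid = ~np.isnan(oob).any(axis=1)
    pred = np.array([classes[0]] * len(y), dtype=object)
    pred[valid] = rf.classes_[np.argmax(oob[valid], axis=1)]
    correct = (pred == y.to_numpy()) & valid
    success = 100.0 * correct.mean()
    mat = pd.crosstab(
        pd.Series(y.to_numpy(), name="true"),
        pd.Series(pred, name="predicted"),
        normalize="index",
    ).reindex(index=classes, columns=classes, fill_value=0.0)
    clf = SpeciesClassifier(
        estimator=rf, features=features, feature_set=feature_set, classes=classes
    )
    report = ConfusionReport(matrix=mat, success=float(success), support=support)
    return clf, report


def predict_species(
    clf: SpeciesClassifier, summaries: pd.DataFrame
) -> pd.DataFrame:
    """Predict species for unlabelled trajectory summaries.

    Returns one row per input trajectory with ``predicted_species``
    (majority vote of the ensemble) and ``vote_fraction`` (fraction of
    trees voting for the winner — low values can be flagged as uncertain).
    Trajectories with missing features get NaN predictions.
    """
    X, rows = _feature_matrix(summaries, clf.features)
    proba = clf.estimator.predict_proba(X.to_numpy())
    winner = np.argmax(proba, axis=1)
    out = pd.DataFrame(
        {
            "predicted_species": pd.array([None] * len(summaries), dtype=object),
            "vote_fraction": np.nan,
        },
        index=summaries.index,
    )
    out.loc[rows, "predicted_species"] = clf.estimator.classes_[winner]
    out.loc[rows, "vote_fraction"] = proba[np.arange(len(winner)), winner]
    if "id" in summaries.columns:
        out.insert(0, "id", summaries["id"])
    return out
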