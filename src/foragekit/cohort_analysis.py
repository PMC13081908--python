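"""Cross-task phenotyping: feature table, PCA, and a sex classifier.

Seven per-session metrics (pellets, pokes, accuracy, win-stay, lose-stay,
retrieval time, poke time) are taken from the deterministic bandit and FR1
tasks (multi-day tasks averaged per mouse), giving a mice x 14 feature
table.  The table is z-scored, decomposed by PCA with a deterministic sign
convention, and fed to a logistic sex classifier evaluated with seeded
stratified cross-validation, summarised by a confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.metrics import confusion_matrix

METRICS = ("pellets", "pokes", "accuracy", "win_stay", "lose_stay",
           "median_retrieval_time_s", "median_poke_time_s")
FEATURE_TASKS = ("bandit_100_0", "fr1")

#: four features per task named in the study's classifier description
RESULTS_FEATURES = tuple(
    f"{task}:{m}" for task in FEATURE_TASKS
    for m in ("accuracy", "win_stay", "pokes", "median_retrieval_time_s")
)
#: six-feature alternative (top |PC1| loadings per the study's methods)
METHODS_FEATURES = tuple(
    f"{task}:{m}" for task in FEATURE_TASKS
    for m in ("median_retrieval_time_s", "win_stay", "accuracy")
)


@dataclass
class FeatureTable:
    data: pd.DataFrame       # index: mouse_id; columns: "<task>:<metric>"
    sex: pd.Series           # aligned with data.index
    cross_task_corr: pd.DataFrame
    excluded: list           # mice dropped for a missing task


@dataclass
class PCAResult:
    loadings: pd.DataFrame            # columns PC1, PC2, ...; index features
    scores: pd.DataFrame              # per-mouse scores
    explained_variance_ratio: np.ndarray
    ranked_pc1: pd.Series             # |PC1| loadings, descending


@dataclass
class SexClassifierReport:
    confusion: pd.DataFrame   # rows true, columns predicted (F, M)
    accuracy: float
    scheme: str
    features: list
    seed: int


def build_feature_table(metrics: pd.DataFrame) -> FeatureTable:
    """Assemble the mice x 14 table from a tidy per-(mouse, task, day) table.

    Multi-day tasks are averaged per mouse before assembly.  Also computes
    the bandit <-> FR1 cross-task correlation for each shared metric.  Mice
    missing either task are listed under ``excluded``.
    """
    sub = metrics[metrics["task"].isin(FEATURE_TASKS)]
    per_mouse = (
        sub.groupby(["mouse_id", "task"])[list(METRICS)].mean().reset_index()
    )
    wide = per_mouse.pivot(index="mouse_id", columns="task", values=list(METRICS))
    wide.columns = [f"{task}:{metric}" for metric, task in wide.columns]
    complete = wide.dropna()
    excluded = sorted(set(wide.index) - set(complete.index))
    order = [f"{task}:{m}" for task in FEATURE_TASKS for m in METRICS]
    complete = complete.loc[:, order]

    corr = pd.Series(
        {
            m: complete[f"bandit_100_0:{m}"].corr(complete[f"fr1:{m}"])
            for m in METRICS
        },
        name="bandit_fr1_corr",
    ).to_frame()

    sex_map = metrics.drop_duplicates("mouse_id").set_index("mouse_id")["sex"]
    return FeatureTable(
        data=complete,
        sex=sex_map.reindex(complete.index),
        cross_task_corr=corr,
        excluded=excluded,
    )


def zscore(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores; raises naming any constant column."""
    sd = df.std(ddof=0)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant feature column(s): {constant}")
    return (df - df.mean()) / sd


def pca_with_loadings(table: FeatureTable, n_components: int | None = None) -> PCAResult:
    """PCA on the z-scored feature table with ranked |PC1| loadings.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making results reproducible across libraries.
    """
    if len(table.data) < 3:
        raise ValueError("need at least 3 mice for PCA")
    Z = zscore(table.data)
    n_components = n_components or min(Z.shape)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Z.to_numpy())
    loadings = pca.components_.T.copy()  # (features, components)
    for j in range(loadings.shape[1]):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    loadings_df = pd.DataFrame(loadings, index=Z.columns, columns=names)
    ranked = loadings_df["PC1"].abs().sort_values(ascending=False)
    return PCAResult(
        loadings=loadings_df,
        scores=pd.DataFrame(scores, index=Z.index, columns=names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        ranked_pc1=ranked,
    )


def classify_sex(
    table: FeatureTable,
    features=RESULTS_FEATURES,
    n_splits: int = 5,
    seed: int = 0,
) -> SexClassifierReport:
    """Cross-validated logistic classification of sex from behaviour.

    Stratified K-fold with within-fold scaling (the held-out mouse never
    contributes to its own scaler or fit); the confusion matrix aggregates
    predictions over held-out folds.
    """
    features = list(features)
    if not features:
        raise ValueError("feature subset is empty")
    X = table.data.loc[:, features].to_numpy()
    y = table.sex.to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both sexes must be present")
    counts = pd.Series(y).value_counts()
    if counts.min() < n_splits:
        raise ValueError(
            f"smallest class ({counts.min()}) below n_splits={n_splits}; "
            "reduce folds or add mice"
        )
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    model = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
    y_pred = cross_val_predict(model, X, y, cv=cv)
    cm = confusion_matrix(y, y_pred, labels=["F", "M"])
    confusion = pd.DataFrame(
        cm, index=["true_F", "true_M"], columns=["pred_F", "pred_M"]
    )
    return SexClassifierReport(
        confusion=confusion,
        accuracy=float((y_pred == y).mean()),
        scheme=f"stratified {n_splits}-fold (shuffled, seed={seed})",
        features=features,
        seed=seed,
    )
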