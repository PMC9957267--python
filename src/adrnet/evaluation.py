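"""Per-ADR classifier evaluation with SMOTE-balanced cross-validation.

For every ADR associated with at least ``min_frequency`` drugs, each
classifier is scored by 10-fold cross-validated AUROC on a ladder of
feature sets: the 10 PCA components alone (baseline), then with network
feature columns added cumulatively (D, DW, DWE, ... up to all ten).  When a
training fold's positive/negative ratio falls below the trigger ratio it is
rebalanced with SMOTE; test folds are never touched.  Feature importance is
read off Wald p-values of an unpenalised logistic regression per ADR.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .centrality import LETTER_TO_COLUMN, all_features
from .dataset_io import IncidenceMatrix
from .network_build import normalize_weights, project_bipartite
from .preprocess import SmoteConfig, fit_pca, smote_oversample, transform_pca

__all__ = [
    "DEFAULT_LADDER",
    "CLASSIFIER_NAMES",
    "PipelineConfig",
    "CVResult",
    "EvaluationReport",
    "filter_adrs",
    "assemble_features",
    "rank_auroc",
    "make_classifier",
    "crossval_auroc",
    "lr_feature_pvalues",
    "aggregate_report",
    "run_evaluation",
    "write_report",
]

#: cumulative feature ladder; "" is the PCA-only baseline
DEFAULT_LADDER = (
    "",
    "D",
    "DW",
    "DWE",
    "DWEO",
    "DWEOC",
    "DWEOCB",
    "DWEOCBA",
    "DWEOCBAH",
    "DWEOCBAHT",
    "DWEOCBAHTP",
)

CLASSIFIER_NAMES = ("LR", "DT", "XGB", "RF", "SVM", "KNN", "ANN")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the per-ADR evaluation loop.

    ``min_frequency`` must be at least ``n_folds`` so that, in most fold
    draws, every test fold can contain a positive example.
    """

    min_frequency: int = 15
    n_folds: int = 10
    feature_ladder: tuple[str, ...] = DEFAULT_LADDER
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    n_pca_components: int = 10
    stratified: bool = False
    standardize_network: bool = False
    pca_per_fold: bool = False
    holdout_adr_edges: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_frequency < self.n_folds:
            raise ValueError("min_frequency must be >= n_folds")
        for step in self.feature_ladder:
            unknown = set(step) - set(LETTER_TO_COLUMN)
            if unknown:
                raise ValueError(f"unknown network feature letters: {sorted(unknown)}")
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")


def filter_adrs(incidence: IncidenceMatrix, min_frequency: int) -> list[str]:
    """ADRs associated with at least ``min_frequency`` drugs, in original
    column order."""
    counts = incidence.values.sum(axis=0)
    return [a for a, c in zip(incidence.adr_ids, counts) if c >= min_frequency]


def assemble_features(
    pca_features: pd.DataFrame, net_features: pd.DataFrame, letters: str
) -> pd.DataFrame:
    """PCA columns plus the network columns named by ``letters``, in ladder
    order.  ``letters=""`` returns the baseline unchanged."""
    cols = []
    for letter in letters:
        if letter not in LETTER_TO_COLUMN:
            raise ValueError(f"unknown network feature letter {letter!r}")
        cols.append(LETTER_TO_COLUMN[letter])
    if not cols:
        return pca_features.copy()
    if list(pca_features.index) != list(net_features.index):
        raise ValueError("PCA and network feature tables must share drug ordering")
    return pd.concat([pca_features, net_features[cols]], axis=1)


def rank_auroc(scores, labels) -> float:
    """AUROC as the Mann–Whitney rank statistic; tied scores count 0.5.

    Equals the probability that a uniformly chosen positive outscores a
    uniformly chosen negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def make_classifier(name: str, seed: int = 0):
    """Fresh estimator for one of the seven classifier names."""
    if name == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if name == "RF":
        return RandomForestClassifier(max_depth=10, random_state=seed)
    if name == "SVM":
        return SVC(random_state=seed)  # decision_function used for ranking
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "ANN":
        return MLPClassifier(
            hidden_layer_sizes=(32,), solver="adam", max_iter=300, random_state=seed
        )
    if name == "XGB":
        from xgboost import XGBClassifier

        grid = {"max_depth": [3, 6], "learning_rate": [0.1, 0.3]}
        est = XGBClassifier(
            n_estimators=100, random_state=seed, verbosity=0, eval_metric="logloss"
        )
        return GridSearchCV(est, grid, cv=3, scoring="roc_auc", error_score=0.5, n_jobs=1)
    raise ValueError(f"unknown classifier {name!r}")


def _scores_of(clf, x: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(x)[:, 1]
    return clf.decision_function(x)


@dataclass
class CVResult:
    mean_auroc: float
    mean_accuracy: float
    fold_aurocs: list[float]
    fold_accuracies: list[float]
    #: folds whose test split held a single class (no AUROC contribution)
    single_class_folds: int = 0
    #: folds where the classifier raised and was skipped
    failed_folds: int = 0


def _cv_loop(y: np.ndarray, config: PipelineConfig, build_xy, classifier: str) -> CVResult:
    """Shared fold loop; ``build_xy(train_idx, test_idx)`` returns the fold's
    (X_train, X_test) so per-fold feature fitting can be plugged in."""
    splitter_cls = StratifiedKFold if config.stratified else KFold
    splitter = splitter_cls(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    aurocs: list[float] = []
    accs: list[float] = []
    single, failed = 0, 0
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y)):
        x_tr, x_te = build_xy(tr, te)
        y_tr, y_te = y[tr], y[te]
        n_pos, n_neg = int(y_tr.sum()), int(len(y_tr) - y_tr.sum())
        if n_pos >= 2 and n_neg > 0 and n_pos / n_neg < config.smote.trigger_ratio:
            fold_cfg = replace(config.smote, seed=config.smote.seed + 1000 + fold)
            x_tr, y_tr = smote_oversample(x_tr, y_tr, fold_cfg)
        clf = make_classifier(classifier, config.seed)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(x_tr, y_tr)
                scores = _scores_of(clf, x_te)
                preds = clf.predict(x_te)
        except Exception:
            failed += 1
            continue
        accs.append(float((preds == y_te).mean()))
        if len(np.unique(y_te)) < 2:
            single += 1
            continue
        aurocs.append(rank_auroc(scores, y_te))
    mean_auroc = float(np.mean(aurocs)) if aurocs else float("nan")
    mean_acc = float(np.mean(accs)) if accs else float("nan")
    return CVResult(mean_auroc, mean_acc, aurocs, accs, single, failed)


def crossval_auroc(x, y, classifier: str, config: PipelineConfig) -> CVResult:
    """Seeded shuffled K-fold cross-validation of one classifier.

    Training folds whose positive/negative ratio is below the SMOTE trigger
    are rebalanced (training portion only); AUROC is the rank statistic of
    predicted scores on the untouched test fold; folds with a single test
    class contribute accuracy but no AUROC and are flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes present overall")
    return _cv_loop(y, config, lambda tr, te: (x[tr], x[te]), classifier)


def lr_feature_pvalues(x, y, config: PipelineConfig, method: str = "wald") -> pd.Series | None:
    """Per-feature p-values of an unpenalised logistic regression.

    ``method="wald"`` (default) gives two-sided Wald p-values from the
    asymptotic covariance (inverse observed information) of a binomial GLM
    fitted by iteratively reweighted least squares; ``method="lr"`` gives
    likelihood-ratio p-values from single-feature-deletion refits.  The
    full set for the ADR is SMOTE-balanced first when the trigger rule
    fires.  Returns one p-value per feature column, or ``None`` when the
    fit fails to converge or yields non-finite values (such ADRs are
    excluded from aggregates and logged by the caller).
    """
    columns = list(x.columns) if isinstance(x, pd.DataFrame) else None
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_neg > 0 and n_pos >= 2 and n_pos / n_neg < config.smote.trigger_ratio:
        x, y = smote_oversample(x, y, config.smote)

    if method not in ("wald", "lr"):
        raise ValueError(f"unknown p-value method {method!r}")

    def _fit(design):
        return sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)

    design = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _fit(design)
            if not res.converged:
                return None
            # (quasi-)separation: fitted probabilities reproduce the labels,
            # Wald statistics are then meaningless (Hauck-Donner collapse)
            if np.max(np.abs(y - res.fittedvalues)) < 1e-4:
                return None
            if method == "wald":
                pvals = np.asarray(res.pvalues)[1:]  # drop intercept
            else:
                from scipy.stats import chi2

                pvals = np.empty(x.shape[1])
                for j in range(x.shape[1]):
                    reduced = _fit(np.delete(design, j + 1, axis=1))
                    stat = max(0.0, 2.0 * (res.llf - reduced.llf))
                    pvals[j] = chi2.sf(stat, df=1)
    except Exception:  # separation, singular information matrix
        return None
    if not np.all(np.isfinite(pvals)):
        return None
    if columns is None:
        columns = [f"x{i}" for i in range(len(pvals))]
    return pd.Series(pvals, index=columns, name="p_value")


@dataclass
class EvaluationReport:
    """Aggregated evaluation output.

    ``results`` is the long-form per-(ADR, classifier, feature-set) table;
    ``ladder_table`` the classifier × feature-set mean-AUROC matrix;
    ``adr_ranking`` the per-ADR best AUROC with/without network features and
    the improvement; ``pvalue_summary`` the mean/SD of logistic-regression
    p-values per network feature; ``pvalue_distributions`` the raw per-ADR
    p-values; ``feature_correlation`` the Pearson matrix of the ten network
    feature columns.
    """

    results: pd.DataFrame
    ladder_table: pd.DataFrame
    adr_ranking: pd.DataFrame
    pvalue_summary: pd.DataFrame
    pvalue_distributions: pd.DataFrame
    feature_correlation: pd.DataFrame
    skipped: list[str] = field(default_factory=list)


def aggregate_report(
    results: pd.DataFrame,
    pvalues: pd.DataFrame,
    net_features: pd.DataFrame,
    ladder: tuple[str, ...] = DEFAULT_LADDER,
    skipped: list[str] | None = None,
) -> EvaluationReport:
    """Aggregate long-form CV records into the report tables."""
    present = [s for s in ladder if s in set(results["feature_set"])]
    ladder_table = (
        results.pivot_table(
            index="classifier", columns="feature_set", values="mean_auroc", aggfunc="mean"
        )
        .reindex(columns=present)
    )
    ladder_table.columns = ["baseline" if c == "" else f"baseline+{c}" for c in present]

    baseline_step, full_step = present[0], present[-1]
    rows = []
    for adr, grp in results.groupby("adr_id", sort=False):
        base = grp[grp["feature_set"] == baseline_step]
        full = grp[grp["feature_set"] == full_step]
        if base.empty or full.empty:
            continue
        best_full = full.loc[full["mean_auroc"].idxmax()]
        rows.append(
            {
                "adr_id": adr,
                "auroc_without_network": float(base["mean_auroc"].max()),
                "auroc_with_network": float(best_full["mean_auroc"]),
                "improvement": float(best_full["mean_auroc"] - base["mean_auroc"].max()),
                "accuracy_with_network": float(best_full["mean_accuracy"]),
                "best_classifier": str(best_full["classifier"]),
            }
        )
    adr_ranking = pd.DataFrame(rows).sort_values(
        "auroc_with_network", ascending=False, ignore_index=True
    ) if rows else pd.DataFrame(rows)

    if len(pvalues):
        pvalue_summary = pd.DataFrame(
            {"mean_p_value": pvalues.mean(axis=0), "sd_p_value": pvalues.std(axis=0, ddof=1)}
        )
    else:
        pvalue_summary = pd.DataFrame(columns=["mean_p_value", "sd_p_value"])

    return EvaluationReport(
        results=results,
        ladder_table=ladder_table,
        adr_ranking=adr_ranking,
        pvalue_summary=pvalue_summary,
        pvalue_distributions=pvalues,
        feature_correlation=net_features.corr(),
        skipped=list(skipped or []),
    )


def _network_feature_table(incidence: IncidenceMatrix, exclude_adr: str | None = None):
    if exclude_adr is None:
        inc = incidence
    else:
        keep = [j for j, a in enumerate(incidence.adr_ids) if a != exclude_adr]
        inc = IncidenceMatrix(
            list(incidence.drug_ids),
            [incidence.adr_ids[j] for j in keep],
            incidence.values[:, keep],
        )
    return all_features(normalize_weights(project_bipartite(inc)))


def run_evaluation(
    incidence: IncidenceMatrix, one_hot, config: PipelineConfig | None = None
) -> EvaluationReport:
    """Full pipeline: network + centralities from the incidence, PCA of the
    one-hot drug features, then the per-ADR / per-classifier / per-ladder
    cross-validation loop and the logistic-regression p-value analysis.

    The network is built once from the full incidence (so the target ADR's
    own associations inform the features, as in the original design) unless
    ``config.holdout_adr_edges`` asks for the leakage-free variant that
    rebuilds the network without the target ADR's column.  PCA is fit once
    on all drugs unless ``config.pca_per_fold``.
    """
    config = config or PipelineConfig()
    x_onehot = one_hot.to_numpy(dtype=float) if isinstance(one_hot, pd.DataFrame) else np.asarray(one_hot, dtype=float)
    drug_ids = list(incidence.drug_ids)

    net = _network_feature_table(incidence)
    if config.standardize_network:
        net = (net - net.mean()) / net.std(ddof=0).replace(0.0, 1.0)

    pca_model = fit_pca(x_onehot, config.n_pca_components)
    pca_frame = transform_pca(pca_model, x_onehot, drug_ids)

    eligible = filter_adrs(incidence, config.min_frequency)
    adr_index = {a: j for j, a in enumerate(incidence.adr_ids)}
    skipped: list[str] = []
    records = []
    pvalue_rows = {}

    for adr in eligible:
        y = incidence.values[:, adr_index[adr]].astype(int)
        net_adr = _network_feature_table(incidence, exclude_adr=adr) if config.holdout_adr_edges else net
        for step in config.feature_ladder:
            feats = assemble_features(pca_frame, net_adr, step)
            for clf_name in config.classifiers:
                if config.pca_per_fold:
                    net_cols = feats.drop(columns=pca_frame.columns).to_numpy(dtype=float)

                    def build(tr, te):
                        model = fit_pca(x_onehot[tr], config.n_pca_components)
                        xtr = transform_pca(model, x_onehot[tr]).to_numpy()
                        xte = transform_pca(model, x_onehot[te]).to_numpy()
                        return (
                            np.hstack([xtr, net_cols[tr]]),
                            np.hstack([xte, net_cols[te]]),
                        )

                    cv = _cv_loop(y, config, build, clf_name)
                else:
                    cv = crossval_auroc(feats.to_numpy(dtype=float), y, clf_name, config)
                records.append(
                    {
                        "adr_id": adr,
                        "classifier": clf_name,
                        "feature_set": step,
                        "mean_auroc": cv.mean_auroc,
                        "mean_accuracy": cv.mean_accuracy,
                        "n_auroc_folds": len(cv.fold_aurocs),
                        "single_class_folds": cv.single_class_folds,
                        "failed_folds": cv.failed_folds,
                    }
                )
        full_feats = assemble_features(pca_frame, net_adr, config.feature_ladder[-1])
        pvals = lr_feature_pvalues(full_feats, y, config)
        if pvals is None:
            skipped.append(f"{adr}: logistic regression p-value fit failed or separated")
        else:
            net_cols_only = [c for c in pvals.index if c in net.columns]
            pvalue_rows[adr] = pvals[net_cols_only]

    results = pd.DataFrame.from_records(records)
    pvalues = pd.DataFrame(pvalue_rows).T if pvalue_rows else pd.DataFrame()
    return aggregate_report(results, pvalues, net, config.feature_ladder, skipped)


def write_report(report: EvaluationReport, out_dir) -> None:
    """Emit the report as TSV tables plus a JSON index and skipped-ADR log."""
    os.makedirs(out_dir, exist_ok=True)
    report.results.to_csv(os.path.join(out_dir, "results.tsv"), sep="\t", index=False)
    report.ladder_table.to_csv(os.path.join(out_dir, "ladder_auroc.tsv"), sep="\t")
    report.adr_ranking.to_csv(os.path.join(out_dir, "adr_ranking.tsv"), sep="\t", index=False)
    report.pvalue_summary.to_csv(os.path.join(out_dir, "pvalue_summary.tsv"), sep="\t")
    report.pvalue_distributions.to_csv(os.path.join(out_dir, "pvalue_distributions.tsv"), sep="\t")
    report.feature_correlation.to_csv(os.path.join(out_dir, "feature_correlation.tsv"), sep="\t")
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(
            {
                "n_adrs_evaluated": int(report.results["adr_id"].nunique()) if len(report.results) else 0,
                "classifiers": sorted(report.results["classifier"].unique().tolist()) if len(report.results) else [],
                "skipped": report.skipped,
            },
            fh,
            indent=2,
        )
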