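"""Age-deconfounded random-forest diagnosis of benign polyps and tumor stages.

The staging model works in two screens.  First, a random-forest *regression*
of host age on relative abundances — fitted on benign-polyp (control)
training samples only — ranks age-discriminatory lineages; the minimal
informative set is chosen from a 10-fold cross-validation error curve over
nested top-feature subsets (1-SE rule) and excluded from everything
downstream, removing the ontogenic confound.  Second, a random-forest
*classifier* of group (BP, T1-T4) on the remaining lineages ranks
stage-discriminatory features; the top-k (default 15 at ASV rank) form the
final model.  A sample is diagnosed as the class holding at least 50% of
tree votes, otherwise as the plurality class with a low-confidence flag.
Reports mirror a 5x5 observed-by-diagnosed confusion matrix with overall and
per-class accuracy and a count of cancer samples diagnosed as BP (the false
negatives the screening application cares most about).

Both screens can be repeated at every taxonomic rank (phylum through genus,
plus ASV) to pick the rank with the best overall accuracy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold, StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .prep import GROUPS, STAGES, collapse_rank, to_relative

logger = logging.getLogger(__name__)

#: fixed class order used for reporting and vote tie-breaking
CLASS_ORDER = ("T1", "T2", "T3", "T4", "BP")

#: ranks swept when choosing the best taxonomic level
SWEEP_RANKS = ("phylum", "class", "order", "family", "genus", "asv")

DEFAULT_N_TREES = 500  # randomForest-style default


# ---------------------------------------------------------------------------
# containers


@dataclass
class FeatureScreenResult:
    rank: str
    importances: pd.Series        # all features, descending importance
    cv_sizes: list                # tested subset sizes (descending)
    cv_errors: list               # mean CV error per size
    cv_se: list                   # standard error per size
    selected: list                # minimal top-feature set (1-SE rule)
    score: float                  # CV R^2 (regression) or accuracy (classification)


@dataclass
class StageModel:
    rank: str
    features: list
    excluded: list
    forest: RandomForestClassifier
    classes: tuple = CLASS_ORDER
    vote_cutoff: float = 0.5

    def __post_init__(self):
        overlap = set(self.features) & set(self.excluded)
        if overlap:
            raise InputError(f"final features overlap excluded set: {overlap}")
        if not 0 < self.vote_cutoff <= 1:
            raise InputError("vote cutoff must be in (0,1]")


@dataclass
class DiagnosisReport:
    confusion: pd.DataFrame       # observed x diagnosed, CLASS_ORDER both ways
    overall_accuracy: float
    per_class_accuracy: pd.Series
    false_negatives: int          # cancer samples diagnosed BP
    votes: pd.DataFrame = None    # per-sample class vote fractions
    diagnosed: pd.Series = None
    low_confidence: pd.Series = None


# ---------------------------------------------------------------------------
# cohort split


def split_cohort(metadata: pd.DataFrame, train_fraction: float = 67 / 95,
                 seed=None, group_col: str = "group"):
    """Group-stratified train/test split, deterministic given ``seed``.

    Per-group training counts are the rounded group share, adjusted by
    largest remainder so the total matches ``round(n * train_fraction)``.
    On the default 95-sample cohort this yields 67 training samples of
    which 32 are BP.
    """
    rng = np.random.default_rng(seed)
    groups = metadata[group_col]
    n_total = len(metadata)
    target = int(round(n_total * train_fraction))
    sizes = groups.value_counts()
    if (sizes < 2).any():
        small = sizes.index[sizes < 2][0]
        raise InputError(f"group {small!r} too small to stratify")
    exact = sizes * train_fraction
    alloc = exact.round().astype(int)
    # keep at least one sample per group on each side
    alloc = alloc.clip(lower=1, upper=sizes - 1)
    while alloc.sum() != target:
        resid = exact - alloc
        if alloc.sum() < target:
            g = resid.idxmax()
            if alloc[g] < sizes[g] - 1:
                alloc[g] += 1
            else:
                resid[g] = -np.inf
                continue
        else:
            g = resid.idxmin()
            if alloc[g] > 1:
                alloc[g] -= 1
            else:
                resid[g] = np.inf
                continue
    train = []
    for g in sizes.index:
        members = metadata.index[groups == g].to_numpy()
        chosen = rng.choice(members, size=int(alloc[g]), replace=False)
        train.extend(chosen)
    train = pd.Index(sorted(train))
    test = metadata.index.difference(train)
    return train, test


# ---------------------------------------------------------------------------
# screens


def _halving_sizes(p: int) -> list[int]:
    sizes = []
    s = p
    while s >= 1:
        sizes.append(int(s))
        if s == 1:
            break
        s = math.ceil(s / 2)
    return sizes


def _pick_size(sizes, errors, ses, rule: str = "min") -> int:
    """Choose the feature-subset size from a CV error curve.

    ``rule="min"`` takes the size minimizing mean CV error (smallest on
    ties); ``rule="1se"`` takes the smallest size within one standard error
    of that minimum.  With several equally informative, mutually redundant
    features the 1-SE rule collapses to very small subsets (two or three
    redundant predictors already saturate accuracy), so the minimum-error
    rule is the default for screening.
    """
    best = int(np.argmin(errors))
    if rule == "min":
        eligible = [s for s, e in zip(sizes, errors) if e <= errors[best] + 1e-12]
        return min(eligible)
    if rule == "1se":
        limit = errors[best] + ses[best]
        eligible = [s for s, e in zip(sizes, errors) if e <= limit]
        return min(eligible)
    raise InputError(f"unknown CV selection rule {rule!r}")


def age_screen(profile: pd.DataFrame, ages: pd.Series, n_folds: int = 10,
               seed=None, n_estimators: int = DEFAULT_N_TREES,
               rule: str = "min", n_repeats: int = 2) -> FeatureScreenResult:
    """Screen age-discriminatory features on control samples.

    Random-forest regression of age on relative abundances; features are
    ranked by importance, then 10-fold CV RMSE is traced over nested
    top-feature subsets with sizes halving from all features down to one.
    The selected set is the smallest size at the curve's error minimum
    (or within one SE of it with ``rule="1se"``).
    """
    ages = ages.loc[profile.index].astype(float)
    if ages.nunique() < 2:
        raise InputError("host age is constant; cannot screen age features")
    if len(profile) < n_folds:
        n_folds = max(2, len(profile))
        logger.warning("reducing age-screen folds to %d", n_folds)
    x = profile.to_numpy(dtype=float)
    y = ages.to_numpy()
    rng = np.random.default_rng(seed)

    forest = RandomForestRegressor(
        n_estimators=n_estimators, max_features=1 / 3,
        random_state=int(rng.integers(2**31)), oob_score=True,
    )
    forest.fit(x, y)
    importances = pd.Series(forest.feature_importances_, index=profile.columns)
    importances = importances.sort_values(ascending=False)
    ranked = list(importances.index)

    sizes = _halving_sizes(profile.shape[1])
    errors, ses = [], []
    # repeated K-fold: the size comparison near the curve minimum is noisy
    # with a single shuffle at n ~ 45
    folds = []
    for _ in range(n_repeats):
        kf = KFold(n_splits=n_folds, shuffle=True,
                   random_state=int(rng.integers(2**31)))
        folds.extend(kf.split(x))
    for s in sizes:
        feats = [profile.columns.get_loc(f) for f in ranked[:s]]
        fold_rmse = []
        for tr, te in folds:
            rf = RandomForestRegressor(
                n_estimators=n_estimators, max_features=1 / 3,
                random_state=int(rng.integers(2**31)),
            )
            rf.fit(x[np.ix_(tr, feats)], y[tr])
            pred = rf.predict(x[np.ix_(te, feats)])
            fold_rmse.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
        errors.append(float(np.mean(fold_rmse)))
        ses.append(float(np.std(fold_rmse, ddof=1) / np.sqrt(len(fold_rmse))))

    chosen = _pick_size(sizes, errors, ses, rule)
    selected = ranked[:chosen]
    oob_r2 = float(forest.oob_score_)
    return FeatureScreenResult(
        rank="", importances=importances, cv_sizes=sizes, cv_errors=errors,
        cv_se=ses, selected=selected, score=oob_r2,
    )


def stage_screen(profile: pd.DataFrame, groups: pd.Series, excluded=(),
                 top_k: int = 15, n_folds: int = 10, seed=None,
                 n_estimators: int = DEFAULT_N_TREES,
                 compute_cv: bool = False) -> FeatureScreenResult:
    """Screen stage-discriminatory features after removing the excluded set.

    Random-forest classification of group; features ranked by importance;
    the top ``top_k`` are returned.  A CV accuracy curve over halving subset
    sizes is computed when ``compute_cv`` is set.  Folds shrink with a
    warning when the smallest class is below ``n_folds`` (T4 typically is).
    """
    keep = [c for c in profile.columns if c not in set(excluded)]
    sub = profile[keep]
    y = groups.loc[sub.index].astype(str).to_numpy()
    rng = np.random.default_rng(seed)
    min_class = pd.Series(y).value_counts().min()
    if min_class < n_folds:
        n_folds = max(2, int(min_class))
        logger.warning("reducing stage-screen folds to %d", n_folds)

    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt",
        random_state=int(rng.integers(2**31)), oob_score=True,
    )
    x = sub.to_numpy(dtype=float)
    forest.fit(x, y)
    importances = pd.Series(forest.feature_importances_, index=sub.columns)
    importances = importances.sort_values(ascending=False)
    ranked = list(importances.index)
    top_k = min(top_k, len(ranked))
    selected = ranked[:top_k]

    sizes, errors, ses = [], [], []
    if compute_cv:
        sizes = _halving_sizes(len(ranked))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        folds = list(skf.split(x, y))
        for s in sizes:
            feats = [sub.columns.get_loc(f) for f in ranked[:s]]
            fold_err = []
            for tr, te in folds:
                rf = RandomForestClassifier(
                    n_estimators=n_estimators, max_features="sqrt",
                    random_state=int(rng.integers(2**31)),
                )
                rf.fit(x[np.ix_(tr, feats)], y[tr])
                fold_err.append(float(np.mean(rf.predict(x[np.ix_(te, feats)]) != y[te])))
            errors.append(float(np.mean(fold_err)))
            ses.append(float(np.std(fold_err, ddof=1) / np.sqrt(len(fold_err))))

    return FeatureScreenResult(
        rank="", importances=importances, cv_sizes=sizes, cv_errors=errors,
        cv_se=ses, selected=selected, score=float(forest.oob_score_),
    )


def mean_decrease_accuracy(model: "StageModel", profile: pd.DataFrame,
                           groups: pd.Series, n_repeats: int = 10,
                           seed=None) -> pd.Series:
    """Permutation importance (mean decrease accuracy) of the final features."""
    x = profile[model.features].to_numpy(dtype=float)
    y = groups.loc[profile.index].astype(str).to_numpy()
    res = permutation_importance(
        model.forest, x, y, n_repeats=n_repeats,
        random_state=np.random.default_rng(seed).integers(2**31),
        scoring="accuracy",
    )
    return pd.Series(res.importances_mean, index=model.features).sort_values(
        ascending=False
    )


# ---------------------------------------------------------------------------
# fitting and diagnosis


def fit_stage_model(profile: pd.DataFrame, groups: pd.Series, features,
                    excluded=(), rank: str = "asv", seed=None,
                    n_estimators: int = DEFAULT_N_TREES) -> StageModel:
    features = list(features)
    x = profile[features].to_numpy(dtype=float)
    y = groups.loc[profile.index].astype(str).to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt",
        random_state=int(np.random.default_rng(seed).integers(2**31)),
        oob_score=True,
    )
    forest.fit(x, y)
    return StageModel(rank=rank, features=features, excluded=list(excluded),
                      forest=forest)


def _votes_to_diagnosis(votes: pd.DataFrame, cutoff: float):
    """Apply the 50%-vote rule; plurality with a flag when no class reaches it.

    Ties in the plurality fallback break by the fixed class order.
    """
    classes = [c for c in CLASS_ORDER if c in votes.columns]
    diagnosed, low_conf = [], []
    for _, row in votes.iterrows():
        winners = [c for c in classes if row[c] >= cutoff]
        if winners:
            diagnosed.append(max(winners, key=lambda c: row[c]))
            low_conf.append(False)
        else:
            best = max(classes, key=lambda c: (row[c], -classes.index(c)))
            diagnosed.append(best)
            low_conf.append(True)
    return (pd.Series(diagnosed, index=votes.index, name="diagnosed"),
            pd.Series(low_conf, index=votes.index, name="low_confidence"))


def diagnose(model: StageModel, profile: pd.DataFrame,
             observed: pd.Series | None = None) -> DiagnosisReport:
    """Diagnose samples from forest vote fractions.

    Features missing from ``profile`` are zero-filled with a warning.  When
    observed labels are provided a full confusion report is assembled.
    """
    if profile.empty:
        raise InputError("no samples to diagnose")
    missing = [f for f in model.features if f not in profile.columns]
    if missing:
        logger.warning("zero-filling %d missing model features", len(missing))
        profile = profile.copy()
        for f in missing:
            profile[f] = 0.0
    x = profile[model.features].to_numpy(dtype=float)
    proba = model.forest.predict_proba(x)
    votes = pd.DataFrame(proba, index=profile.index,
                         columns=model.forest.classes_)
    diagnosed, low_conf = _votes_to_diagnosis(votes, model.vote_cutoff)
    if observed is None:
        return DiagnosisReport(
            confusion=None, overall_accuracy=np.nan,
            per_class_accuracy=None, false_negatives=0, votes=votes,
            diagnosed=diagnosed, low_confidence=low_conf,
        )
    report = report_from_votes(votes, observed.loc[profile.index],
                               cutoff=model.vote_cutoff)
    return report


def report_from_votes(votes: pd.DataFrame, observed: pd.Series,
                      cutoff: float = 0.5) -> DiagnosisReport:
    """Assemble the 5x5 confusion report from per-sample vote fractions."""
    diagnosed, low_conf = _votes_to_diagnosis(votes, cutoff)
    observed = observed.loc[votes.index].astype(str)
    classes = list(CLASS_ORDER)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for s in votes.index:
        confusion.loc[observed[s], diagnosed[s]] += 1
    overall, per_class = accuracy_from_confusion(confusion)
    fn = int(confusion.loc[list(STAGES), "BP"].sum())
    return DiagnosisReport(
        confusion=confusion, overall_accuracy=overall,
        per_class_accuracy=per_class, false_negatives=fn, votes=votes,
        diagnosed=diagnosed, low_confidence=low_conf,
    )


def accuracy_from_confusion(matrix: pd.DataFrame):
    """Overall (trace/total) and per-class (diagonal/row-sum) accuracy."""
    m = matrix.to_numpy(dtype=float)
    if (m < 0).any():
        raise InputError("confusion matrix entries must be non-negative")
    total = m.sum()
    if total == 0:
        raise InputError("empty confusion matrix")
    overall = float(np.trace(m) / total)
    row_sums = m.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per = np.where(row_sums > 0, np.diag(m) / row_sums, np.nan)
    return overall, pd.Series(per, index=matrix.index, name="accuracy")


# ---------------------------------------------------------------------------
# end-to-end per-rank evaluation


def evaluate_rank(counts: pd.DataFrame, taxonomy: pd.DataFrame,
                  metadata: pd.DataFrame, rank: str, train_idx, test_idx,
                  top_k: int = 15, seed=None,
                  n_estimators: int = DEFAULT_N_TREES,
                  exclude_age: bool = True):
    """Screen -> fit -> diagnose at one taxonomic rank.

    Returns ``(combined_report, test_report, model, age_result)``.  The
    combined Table-style report covers the whole cohort: training samples
    are scored by out-of-bag votes, test samples by ordinary votes, so the
    reported matrix sums to the cohort size.
    """
    collapsed = collapse_rank(counts, taxonomy, rank)
    rel = to_relative(collapsed)
    rng = np.random.default_rng(seed)

    age_result = None
    excluded: list = []
    if exclude_age:
        bp_train = [s for s in train_idx if metadata.loc[s, "group"] == "BP"]
        age_result = age_screen(
            rel.loc[bp_train], metadata["age"], seed=int(rng.integers(2**31)),
            n_estimators=n_estimators,
        )
        excluded = list(age_result.selected)

    screen = stage_screen(
        rel.loc[train_idx], metadata["group"], excluded=excluded, top_k=top_k,
        seed=int(rng.integers(2**31)), n_estimators=n_estimators,
    )
    model = fit_stage_model(
        rel.loc[train_idx], metadata["group"], screen.selected,
        excluded=excluded, rank=rank, seed=int(rng.integers(2**31)),
        n_estimators=n_estimators,
    )
    # combined report: OOB votes for training samples, standard for test
    oob = pd.DataFrame(model.forest.oob_decision_function_,
                       index=pd.Index(train_idx),
                       columns=model.forest.classes_)
    test_votes = pd.DataFrame(
        model.forest.predict_proba(rel.loc[test_idx, model.features].to_numpy()),
        index=pd.Index(test_idx), columns=model.forest.classes_,
    )
    all_votes = pd.concat([oob, test_votes]).loc[metadata.index].fillna(0.0)
    combined = report_from_votes(all_votes, metadata["group"])
    test_report = report_from_votes(test_votes, metadata["group"])
    return combined, test_report, model, age_result


def rank_sweep(counts: pd.DataFrame, taxonomy: pd.DataFrame,
               metadata: pd.DataFrame, seed=None, ranks=SWEEP_RANKS,
               top_k: int = 15, n_estimators: int = DEFAULT_N_TREES,
               train_fraction: float = 67 / 95):
    """Full screen/fit/diagnose cycle per rank; best rank by overall accuracy.

    Ties break toward the finer rank.  Returns ``(reports, chosen_rank)``
    where ``reports[rank]`` holds the combined Table-style report, the
    test-only report and the model.
    """
    rng = np.random.default_rng(seed)
    train_idx, test_idx = split_cohort(metadata, train_fraction,
                                       seed=int(rng.integers(2**31)))
    reports = {}
    for rank in ranks:
        combined, test_rep, model, age_res = evaluate_rank(
            counts, taxonomy, metadata, rank, train_idx, test_idx,
            top_k=top_k, seed=int(rng.integers(2**31)),
            n_estimators=n_estimators,
        )
        reports[rank] = {
            "combined": combined, "test": test_rep, "model": model,
            "age_screen": age_res,
        }
    # argmax accuracy; ties -> finer rank (later in the sweep order)
    chosen = max(
        ranks,
        key=lambda r: (reports[r]["combined"].overall_accuracy,
                       list(ranks).index(r)),
    )
    return reports, chosen


# ---------------------------------------------------------------------------
# bias audit


def audit_bias(correct: pd.Series, metadata: pd.DataFrame) -> pd.DataFrame:
    """Test whether misdiagnosis associates with host age or gender.

    Rank-sum (Mann-Whitney) test of age between correctly and falsely
    diagnosed samples and Fisher's exact test of gender x correctness,
    BH-adjusted across the two tests.  Degenerate when one side is empty.
    """
    correct = correct.astype(bool)
    meta = metadata.loc[correct.index]
    n_true, n_false = int(correct.sum()), int((~correct).sum())
    if n_true == 0 or n_false == 0:
        return pd.DataFrame(
            {"test": ["age_ranksum", "gender_fisher"],
             "statistic": [np.nan, np.nan], "p": [np.nan, np.nan],
             "p_adj": [np.nan, np.nan], "degenerate": [True, True]}
        ).set_index("test")
    age_t = meta.loc[correct, "age"].astype(float)
    age_f = meta.loc[~correct, "age"].astype(float)
    u, p_age = stats.mannwhitneyu(age_t, age_f, alternative="two-sided")
    table = pd.crosstab(meta["gender"], correct)
    table = table.reindex(index=["female", "male"], columns=[False, True],
                          fill_value=0)
    odds, p_gender = stats.fisher_exact(table.to_numpy())
    p_adj = multipletests([p_age, p_gender], method="fdr_bh")[1]
    return pd.DataFrame(
        {"test": ["age_ranksum", "gender_fisher"],
         "statistic": [float(u), float(odds)], "p": [float(p_age), float(p_gender)],
         "p_adj": p_adj, "degenerate": [False, False]}
    ).set_index("test")
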