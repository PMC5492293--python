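"""Ranked cross-validation protocol comparing turn and straight features.

Four tests run in sequence on a cohort's straight- and turn-condition
feature matrices:

I    stratified five-fold CV of all 18 classifier x selector (CM-FS)
     combinations, per condition; the combinations are ranked per metric
     (competition ranking with the shared-minimal-position tie rule) and the
     least successful classifier and selector in the pooled top nine are
     discarded, leaving 10 combinations;
II   repeated stratified 80/20 random-shuffle-split (RSS) CV of the 10
     combinations with per-iteration feature selection; Welch's t-tests
     compare the best straight and best turn combination metric-by-metric;
III  the most frequently occurring (MFO) features of the best Test II
     combination — selected in at least 10% of iterations — form nested
     subsets (all, all-but-last, ..., single most frequent), each re-run
     through RSS CV with the best classifier and no per-iteration selection;
IV   the 592-feature concatenation of both conditions, evaluated with the
     top four Test II classifiers and the two surviving selectors.

All randomness derives from a single base seed via counter-based seed
sequences, so runs are reproducible and individual iterations can be
re-derived in isolation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .features import FeatureMatrix
from .modeling import (
    CLASSIFIER_MODELS,
    METRIC_NAMES,
    POSITIVE_LABEL,
    SELECTOR_METHODS,
    ClassifierSpec,
    SelectorSpec,
    select_features,
    train_and_evaluate,
)

log = logging.getLogger(__name__)

Z_95 = 1.96


def derive_seed(base_seed: int, *keys: int) -> int:
    """Deterministic child seed < 2**31 from a base seed and integer keys."""
    ss = np.random.SeedSequence(int(base_seed) % (2**31),
                                spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % (2**31))


def combo_key(cspec: ClassifierSpec, sspec: SelectorSpec) -> str:
    return f"{cspec.model}|{sspec.method}"


_DISPLAY = {"kNN3": "kNN (k = 3)", "kNN5": "kNN (k = 5)",
            "SVM_linear": "SVM (linear)", "SVM_poly3": "SVM (poly = 3)",
            "SVM_poly5": "SVM (poly = 5)", "RF": "RF"}


def display_name(key: str) -> str:
    model, method = key.split("|")
    return f"{_DISPLAY[model]} {method}"


def default_combos(models=CLASSIFIER_MODELS,
                   methods=SELECTOR_METHODS) -> list[tuple[ClassifierSpec, SelectorSpec]]:
    """The CM-FS grid: every classifier paired with every selector."""
    return [(ClassifierSpec(model=m), SelectorSpec(method=s))
            for m in models for s in methods]


@dataclass
class CVSummary:
    """Per-combination metric distributions and selection frequencies."""

    n_iterations: int
    per_iteration: dict                  # combo key -> metric -> np.ndarray
    selection_counts: dict               # combo key -> Counter(feature -> n)

    @property
    def combos(self) -> list[str]:
        return list(self.per_iteration)

    def mean(self, combo: str, metric: str) -> float:
        return float(np.mean(self.per_iteration[combo][metric]))

    def sd(self, combo: str, metric: str) -> float:
        v = self.per_iteration[combo][metric]
        return float(np.std(v, ddof=1)) if v.size > 1 else 0.0

    def ci(self, combo: str, metric: str) -> float:
        """95% confidence-interval half-width, 1.96 * SD / sqrt(n)."""
        return ci_halfwidth(self.sd(combo, metric), self.n_iterations)

    def table(self) -> pd.DataFrame:
        """Mean/SD/CI per metric per combination (multi-level columns)."""
        rows = {}
        for combo in self.combos:
            row = {}
            for m in METRIC_NAMES:
                row[(m, "mean")] = self.mean(combo, m)
                row[(m, "sd")] = self.sd(combo, m)
                row[(m, "ci")] = self.ci(combo, m)
            rows[combo] = row
        return pd.DataFrame.from_dict(rows, orient="index")


def ci_halfwidth(sd: float, n: int) -> float:
    """95% CI half-width of a mean over n repetitions: 1.96 * SD / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return Z_95 * sd / np.sqrt(n)


@dataclass(frozen=True)
class RankTable:
    """Per-metric competition ranks and their sum, best (lowest sum) first."""

    ranks: pd.DataFrame                  # combos x metrics
    rank_sum: pd.Series                  # combo -> sum, ascending order

    @property
    def ordering(self) -> list[str]:
        return list(self.rank_sum.index)

    @property
    def best(self) -> str:
        return str(self.rank_sum.index[0])


def competition_ranks(scores: np.ndarray) -> np.ndarray:
    """Descending competition ranking with the shared-minimal-position rule.

    The largest score gets rank 1; tied scores share the smallest position of
    the tie, and the next distinct score resumes at its ordinal position
    (e.g. scores [9, 8, 7, 7, 7, 6, 5] -> ranks [1, 2, 3, 3, 3, 6, 7]).
    """
    return sps.rankdata(-np.asarray(scores, dtype=float), method="min").astype(int)


def rank_combinations(summary: CVSummary,
                      metrics: tuple = METRIC_NAMES) -> RankTable:
    """Rank every combination per metric (higher mean = better) and sum."""
    combos = summary.combos
    if not combos:
        raise ValueError("no combinations to rank")
    ranks = pd.DataFrame(index=combos, columns=list(metrics), dtype=int)
    for m in metrics:
        vals = np.array([summary.mean(c, m) for c in combos])
        ranks[m] = competition_ranks(vals)
    rank_sum = ranks.sum(axis=1).sort_values(kind="stable")
    return RankTable(ranks=ranks, rank_sum=rank_sum)


# ---------------------------------------------------------------------------
# split evaluation core


def _subset(fm: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(X=fm.X.iloc[idx], labels=fm.labels.iloc[idx])


def _evaluate_split(data: FeatureMatrix, train_idx: np.ndarray,
                    test_idx: np.ndarray,
                    combos: list[tuple[ClassifierSpec, SelectorSpec]],
                    split_seed: int,
                    fixed_features: list[str] | None = None) -> tuple[dict, dict]:
    """Selection + evaluation of one train/test split.

    Feature selection is computed once per distinct selector and shared by
    the classifiers paired with it.  Returns (metrics by combo key, selected
    features by selector method).
    """
    train = _subset(data, train_idx)
    test = _subset(data, test_idx)
    from .modeling import apply_normalizer, fit_normalizer
    params = fit_normalizer(train)
    train_n = apply_normalizer(params, train)
    test_n = apply_normalizer(params, test)

    selected: dict[str, list[str]] = {}
    s_i = 0
    for _, sspec in combos:
        if sspec.method in selected:
            continue
        if fixed_features is not None:
            selected[sspec.method] = list(fixed_features)
        else:
            seeded = replace(sspec, seed=derive_seed(split_seed, 1, s_i))
            selected[sspec.method] = select_features(seeded, train_n)
        s_i += 1

    results = {}
    for c_i, (cspec, sspec) in enumerate(combos):
        seeded = replace(cspec, seed=derive_seed(split_seed, 2, c_i))
        m = train_and_evaluate(seeded, train_n, test_n, selected[sspec.method])
        results[combo_key(cspec, sspec)] = m
    return results, selected


def _collect(metrics_per_split: list[dict], selections: list[dict],
             combos: list[tuple[ClassifierSpec, SelectorSpec]],
             n_iterations: int) -> CVSummary:
    per_iteration = {}
    counts: dict[str, Counter] = {}
    for cspec, sspec in combos:
        key = combo_key(cspec, sspec)
        per_iteration[key] = {
            m: np.array([ms[key].as_dict()[m] for ms in metrics_per_split])
            for m in METRIC_NAMES
        }
        c: Counter = Counter()
        for sel in selections:
            c.update(sel[sspec.method])
        counts[key] = c
    return CVSummary(n_iterations=n_iterations, per_iteration=per_iteration,
                     selection_counts=counts)


def five_fold_cv(data: FeatureMatrix,
                 combos: list[tuple[ClassifierSpec, SelectorSpec]],
                 seed: int = 0) -> CVSummary:
    """Stratified five-fold CV with per-fold selection and normalization."""
    y = (data.labels == POSITIVE_LABEL).to_numpy()
    if min(np.sum(y), np.sum(~y)) < 5:
        raise ValueError("five-fold CV needs at least 5 samples per class")
    skf = StratifiedKFold(n_splits=5, shuffle=True,
                          random_state=derive_seed(seed, 0))
    metrics_per_split, selections = [], []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        res, sel = _evaluate_split(data, tr, te, combos,
                                   derive_seed(seed, 10, fold))
        metrics_per_split.append(res)
        selections.append(sel)
    return _collect(metrics_per_split, selections, combos, n_iterations=5)


def rss_cv(data: FeatureMatrix,
           combos: list[tuple[ClassifierSpec, SelectorSpec]],
           n_iter: int = 2500, test_frac: float = 0.2, seed: int = 0,
           fixed_features: list[str] | None = None) -> CVSummary:
    """Repeated stratified random-shuffle-split CV (80/20 by default).

    Every iteration draws a fresh stratified split from an iteration-derived
    seed, selects features on the training rows only (unless
    ``fixed_features`` pins the subset), fits and evaluates each combination.
    A split whose test part misses a class is redrawn with the next derived
    seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    y = (data.labels == POSITIVE_LABEL).to_numpy()
    metrics_per_split, selections = [], []
    for i in range(n_iter):
        attempt = 0
        while True:
            split_seed = derive_seed(seed, i, attempt)
            sss = StratifiedShuffleSplit(n_splits=1, test_size=test_frac,
                                         random_state=split_seed)
            tr, te = next(sss.split(np.zeros(len(y)), y))
            if len(np.unique(y[te])) == 2:
                break
            attempt += 1
            log.info("iteration %d: test split missing a class; redrawing", i)
        res, sel = _evaluate_split(data, tr, te, combos, split_seed,
                                   fixed_features)
        metrics_per_split.append(res)
        selections.append(sel)
    return _collect(metrics_per_split, selections, combos, n_iterations=n_iter)


# ---------------------------------------------------------------------------
# Test I pruning


def _top_counts(tables: list[RankTable], top_n: int):
    cls_counts: Counter = Counter()
    sel_counts: Counter = Counter()
    for t in tables:
        for key in t.ordering[:top_n]:
            model, method = key.split("|")
            cls_counts[model] += 1
            sel_counts[method] += 1
    return cls_counts, sel_counts


def _best_rank_sum(entity: str, tables: list[RankTable], is_model: bool) -> float:
    best = np.inf
    for t in tables:
        for key, rs in t.rank_sum.items():
            model, method = key.split("|")
            if (model if is_model else method) == entity:
                best = min(best, rs)
    return best


def prune_after_test1(straight: RankTable, turn: RankTable,
                      top_n: int = 9) -> tuple[list[str], list[str]]:
    """Discard the classifier and selector least present in the top nine.

    Appearances are counted in the pooled straight and turn top-``top_n``
    rows.  Ties go against the candidate whose best (smallest) rank sum
    across both tables is worse (larger).  Returns the kept classifier
    models and selector methods.
    """
    tables = [straight, turn]
    cls_counts, sel_counts = _top_counts(tables, top_n)
    models = [k.split("|")[0] for k in straight.ordering]
    methods = [k.split("|")[1] for k in straight.ordering]
    all_models = sorted(set(models), key=CLASSIFIER_MODELS.index)
    all_methods = sorted(set(methods), key=SELECTOR_METHODS.index)

    def least(entities: list[str], counts: Counter, is_model: bool) -> str:
        low = min(counts.get(e, 0) for e in entities)
        tied = [e for e in entities if counts.get(e, 0) == low]
        if len(tied) > 1:
            tied.sort(key=lambda e: -_best_rank_sum(e, tables, is_model))
        return tied[0]

    drop_model = least(all_models, cls_counts, True)
    drop_method = least(all_methods, sel_counts, False)
    log.info("Test I pruning removed classifier %s and selector %s",
             drop_model, drop_method)
    return ([m for m in all_models if m != drop_model],
            [m for m in all_methods if m != drop_method])


# ---------------------------------------------------------------------------
# Test III: most-frequently-occurring feature subsets


def mfo_features(summary: CVSummary, combo: str, threshold: int,
                 max_features: int | None = None) -> list[str]:
    """Features selected at least ``threshold`` times, most frequent first.

    Frequency ties are broken alphabetically for determinism.
    ``max_features`` truncates the list to the most frequent entries; this
    matters when an unbounded selector (SEL) passes large feature sets every
    iteration, which would make the nested subset sweep quadratic in a long
    tail of equally-frequent features.
    """
    counts = summary.selection_counts[combo]
    chosen = [(f, n) for f, n in counts.items() if n >= threshold]
    chosen.sort(key=lambda fn: (-fn[1], fn[0]))
    ordered = [f for f, _ in chosen]
    return ordered[:max_features] if max_features is not None else ordered


def mfo_subsets(ordered: list[str]) -> list[list[str]]:
    """Nested subsets X_0 (all) down to X_n (single most frequent feature)."""
    if not ordered:
        raise ValueError("empty MFO feature list")
    return [ordered[: len(ordered) - i] for i in range(len(ordered))]


def mfo_sweep(data: FeatureMatrix, summary: CVSummary, combo: str,
              best_classifier: ClassifierSpec, threshold: int = 250,
              n_iter: int = 2500, test_frac: float = 0.2,
              seed: int = 0, max_features: int | None = None) -> dict[int, CVSummary]:
    """RSS CV of every nested MFO subset with a fixed feature list.

    Returns ``{subset size: CVSummary}`` for subsets built from the selection
    frequencies of ``combo`` in ``summary``.
    """
    ordered = mfo_features(summary, combo, threshold, max_features)
    if not ordered:
        raise ValueError(f"no feature reached the MFO threshold {threshold}")
    out = {}
    dummy_sel = SelectorSpec(method="S5B", k=max(1, len(ordered)))
    for subset in mfo_subsets(ordered):
        out[len(subset)] = rss_cv(data, [(best_classifier, dummy_sel)],
                                  n_iter=n_iter, test_frac=test_frac,
                                  seed=derive_seed(seed, len(subset)),
                                  fixed_features=subset)
    return out


# ---------------------------------------------------------------------------
# Welch comparison


def welch_t(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float, float]:
    """Welch's t statistic, Welch-Satterthwaite df, two-sided p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("Welch's t is undefined with zero variance in both samples")
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.size**2 * (a.size - 1))
                   + vb**2 / (b.size**2 * (b.size - 1)))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# the full four-test sequence


@dataclass(frozen=True)
class ProtocolConfig:
    n_iter: int = 2500            # RSS repetitions (Tests II-IV)
    test_frac: float = 0.2        # RSS held-out fraction
    mfo_frac: float = 0.1         # MFO threshold as a fraction of n_iter
    mfo_max_features: int | None = None   # cap on the MFO list (Test III)
    top_n: int = 9                # pruning window after Test I
    n_test4_classifiers: int = 4
    seed: int = 0

    @property
    def mfo_threshold(self) -> int:
        return max(1, int(round(self.mfo_frac * self.n_iter)))


@dataclass
class ProtocolReport:
    """Structured results of Tests I-IV plus the Welch comparisons."""

    config: ProtocolConfig
    test1: dict                    # condition -> CVSummary
    ranks1: dict                   # condition -> RankTable
    kept_classifiers: list
    kept_selectors: list
    test2: dict                    # condition -> CVSummary
    ranks2: dict                   # condition -> RankTable
    welch: dict                    # metric -> (t, df, p) best turn vs straight
    test3: dict                    # condition -> {subset size: CVSummary}
    test3_features: dict           # condition -> ordered MFO list
    test4: CVSummary
    ranks4: RankTable

    def to_dict(self) -> dict:
        def summary_dict(s: CVSummary) -> dict:
            return {
                "n_iterations": s.n_iterations,
                "metrics": {c: {m: {"mean": s.mean(c, m), "sd": s.sd(c, m),
                                    "ci": s.ci(c, m)} for m in METRIC_NAMES}
                            for c in s.combos},
                "selection_counts": {c: dict(s.selection_counts[c])
                                     for c in s.combos},
            }

        def rank_dict(r: RankTable) -> dict:
            return {"rank_sum": {k: int(v) for k, v in r.rank_sum.items()},
                    "ordering": r.ordering}

        return {
            "config": {k: getattr(self.config, k) for k in
                       ("n_iter", "test_frac", "mfo_frac", "mfo_max_features",
                        "top_n", "n_test4_classifiers", "seed")},
            "test1": {c: summary_dict(s) for c, s in self.test1.items()},
            "ranks1": {c: rank_dict(r) for c, r in self.ranks1.items()},
            "kept_classifiers": self.kept_classifiers,
            "kept_selectors": self.kept_selectors,
            "test2": {c: summary_dict(s) for c, s in self.test2.items()},
            "ranks2": {c: rank_dict(r) for c, r in self.ranks2.items()},
            "welch": {m: {"t": t, "df": df, "p": p}
                      for m, (t, df, p) in self.welch.items()},
            "test3": {c: {str(k): summary_dict(s) for k, s in d.items()}
                      for c, d in self.test3.items()},
            "test3_features": self.test3_features,
            "test4": summary_dict(self.test4),
            "ranks4": rank_dict(self.ranks4),
        }


def combine_matrices(straight: FeatureMatrix, turn: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation with condition prefixes (592 features)."""
    if not straight.X.index.equals(turn.X.index):
        raise ValueError("straight and turn matrices must share participants")
    if not straight.labels.equals(turn.labels):
        raise ValueError("straight and turn labels disagree")
    X = pd.concat([straight.X.add_prefix("straight|"),
                   turn.X.add_prefix("turn|")], axis=1)
    return FeatureMatrix(X=X, labels=straight.labels)


def run_protocol(straight: FeatureMatrix, turn: FeatureMatrix,
                 config: ProtocolConfig = ProtocolConfig()) -> ProtocolReport:
    """Execute Tests I-IV on a cohort's straight and turn feature matrices."""
    conditions = {"straight": straight, "turn": turn}
    seed = config.seed

    combos18 = default_combos()
    test1 = {c: five_fold_cv(fm, combos18, seed=derive_seed(seed, 1))
             for c, fm in conditions.items()}
    ranks1 = {c: rank_combinations(s) for c, s in test1.items()}

    kept_cls, kept_sel = prune_after_test1(ranks1["straight"], ranks1["turn"],
                                           top_n=config.top_n)
    combos10 = default_combos(models=kept_cls, methods=kept_sel)

    test2 = {c: rss_cv(fm, combos10, n_iter=config.n_iter,
                       test_frac=config.test_frac,
                       seed=derive_seed(seed, 2, i))
             for i, (c, fm) in enumerate(conditions.items())}
    ranks2 = {c: rank_combinations(s) for c, s in test2.items()}

    best = {c: ranks2[c].best for c in conditions}
    welch = {}
    for m in METRIC_NAMES:
        a = test2["turn"].per_iteration[best["turn"]][m]
        b = test2["straight"].per_iteration[best["straight"]][m]
        try:
            welch[m] = welch_t(a, b)
        except ValueError:
            log.warning("Welch comparison undefined for metric %s", m)

    test3, test3_features = {}, {}
    for c, fm in conditions.items():
        best_model = best[c].split("|")[0]
        cspec = ClassifierSpec(model=best_model)
        mfo = mfo_features(test2[c], best[c], config.mfo_threshold,
                           config.mfo_max_features)
        test3_features[c] = mfo
        if mfo:
            test3[c] = mfo_sweep(fm, test2[c], best[c], cspec,
                                 threshold=config.mfo_threshold,
                                 n_iter=config.n_iter,
                                 test_frac=config.test_frac,
                                 seed=derive_seed(seed, 3),
                                 max_features=config.mfo_max_features)
        else:
            log.warning("no MFO features for condition %s; Test III skipped", c)
            test3[c] = {}

    # Test IV reads the Test II *turn* ranking for its top classifiers
    turn_order_models = []
    for key in ranks2["turn"].ordering:
        model = key.split("|")[0]
        if model not in turn_order_models:
            turn_order_models.append(model)
    top4 = turn_order_models[: config.n_test4_classifiers]
    combined = combine_matrices(straight, turn)
    combos8 = default_combos(models=top4, methods=kept_sel)
    test4 = rss_cv(combined, combos8, n_iter=config.n_iter,
                   test_frac=config.test_frac, seed=derive_seed(seed, 4))
    ranks4 = rank_combinations(test4)

    return ProtocolReport(config=config, test1=test1, ranks1=ranks1,
                          kept_classifiers=kept_cls, kept_selectors=kept_sel,
                          test2=test2, ranks2=ranks2, welch=welch,
                          test3=test3, test3_features=test3_features,
                          test4=test4, ranks4=ranks4)


__all__ = [
    "Z_95", "derive_seed", "combo_key", "display_name", "default_combos",
    "CVSummary", "ci_halfwidth", "RankTable", "competition_ranks",
    "rank_combinations", "five_fold_cv", "rss_cv", "prune_after_test1",
    "mfo_features", "mfo_subsets", "mfo_sweep", "welch_t",
    "ProtocolConfig", "ProtocolReport", "combine_matrices", "run_protocol",
]
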