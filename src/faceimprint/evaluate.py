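"""The megastudy statistical engine.

Individual-grouped repeated k-fold cross-validation, tie-aware AUC,
Normal-approximation p-values, Benjamini-Hochberg step-up selection, the
2-standard-error criterion, and one-sided Welch comparisons between nested
input sets.

The AUC sampling distribution is treated as approximately Normal; for each
variable the mean and standard error are estimated from the k AUC values
observed across cross-validation cells, and the p-value is the area to the
left of 0.5 under the fitted Normal (H0: AUC <= 0.5).  The SE of the mean
is sd/sqrt(k) without a correction for the correlation between CV cells —
a known source of bias in cross-validation variance estimates, so
"significant" should be read with that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import ConfigError, derive_seed

__all__ = [
    "CVPlan",
    "AUCResult",
    "BHResult",
    "compute_auc",
    "make_cv_plan",
    "run_cv",
    "summarize_auc",
    "bh_select",
    "two_se_select",
    "welch_onesided",
    "count_significant",
    "percent_increase",
    "ranking_table",
]

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-12


def compute_auc(scores, labels) -> float | None:
    """Tie-aware AUC: P(score+ > score-) + 0.5 P(tie), via the
    Mann-Whitney U identity on midranks.

    Returns None when only one class is present (the fold is then skipped,
    reducing k for sparse variables).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ConfigError("scores and labels must be aligned 1-D arrays")
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return None
    ranks = stats.rankdata(scores)  # midranks handle ties as 1/2
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class CVPlan:
    """Fold assignment at the individual level, per repeat.

    ``assignment[r, i]`` is the fold of sorted-unique individual i in
    repeat r; every image of an individual therefore lands in exactly one
    fold per repeat, and fold sizes (in individuals) differ by at most 1.
    """

    individuals: np.ndarray  # sorted unique ids
    assignment: np.ndarray  # (n_repeats, n_individuals) fold indices
    n_repeats: int
    n_folds: int
    seed: int

    def cells(self):
        for r in range(self.n_repeats):
            for f in range(self.n_folds):
                yield r, f

    def fold_of_rows(self, individual_id: np.ndarray, repeat: int) -> np.ndarray:
        idx = np.searchsorted(self.individuals, individual_id)
        return self.assignment[repeat, idx]

    def split_rows(self, individual_id: np.ndarray, repeat: int, fold: int):
        folds = self.fold_of_rows(np.asarray(individual_id), repeat)
        test = np.flatnonzero(folds == fold)
        train = np.flatnonzero(folds != fold)
        return train, test


def make_cv_plan(attrs, n_repeats: int = 20, n_folds: int = 5, seed: int = 0) -> CVPlan:
    """Randomly partition individuals into near-equal folds, per repeat."""
    ids = np.unique(np.asarray(attrs.individual_id))
    if ids.size < n_folds:
        raise ConfigError(
            f"{ids.size} individuals cannot be split into {n_folds} folds"
        )
    rng = np.random.default_rng(derive_seed(seed, "cv-plan"))
    assignment = np.empty((n_repeats, ids.size), dtype=np.int64)
    for r in range(n_repeats):
        perm = rng.permutation(ids.size)
        assignment[r, perm] = np.arange(ids.size) % n_folds
    return CVPlan(
        individuals=ids,
        assignment=assignment,
        n_repeats=n_repeats,
        n_folds=n_folds,
        seed=seed,
    )


@dataclass
class AUCResult:
    """Cross-validated AUC summary for one variable."""

    name: str
    measures: np.ndarray  # defined AUCs only, length k
    mean: float | None = None
    se: float | None = None
    p_value: float | None = None
    two_se_significant: bool | None = None
    bh_significant: bool | None = None

    @property
    def k(self) -> int:
        return len(self.measures)


def summarize_auc(measures) -> tuple[float, float, float] | None:
    """(mean, SE, p) from k >= 2 defined AUC measures; None otherwise.

    SE = sd(measures, ddof=1)/sqrt(k); p = Phi((0.5 - mean)/SE), i.e. the
    Normal-CDF area left of 0.5.  A mean of exactly 0.5 (or zero spread at
    the null) gives p = 0.5.
    """
    m = np.asarray([x for x in measures if x is not None], dtype=np.float64)
    if m.size < 2:
        return None
    mean = float(m.mean())
    se = float(m.std(ddof=1) / np.sqrt(m.size))
    if mean == 0.5:
        p = 0.5
    elif se == 0.0:
        p = _P_FLOOR if mean > 0.5 else _P_CEIL
    else:
        p = float(stats.norm.cdf((0.5 - mean) / se))
        p = min(max(p, _P_FLOOR), _P_CEIL)
    return mean, se, p


def two_se_select(mean: float, se: float) -> bool:
    """Lower 2SE confidence bound strictly above the 0.5 random threshold."""
    return mean - 2.0 * se > 0.5


@dataclass
class BHResult:
    """Benjamini-Hochberg step-up selection at level q."""

    q: float
    cutoff: float | None
    rejected: list = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    @property
    def expected_false_positives(self) -> float:
        return self.q * self.n_rejected


def bh_select(p_values, q: float = 0.05, names=None) -> BHResult:
    """Step-up rule: largest i with p_(i) <= i*q/m; reject all p <= p_(i).

    Controls E[fp/(tp+fp)] <= q over the m variables with a defined
    p-value (undefined/None entries are excluded before ranking).
    """
    if names is None:
        names = list(range(len(p_values)))
    pairs = [(p, nm) for p, nm in zip(p_values, names) if p is not None]
    if not pairs:
        return BHResult(q=q, cutoff=None)
    p = np.array([x[0] for x in pairs])
    if np.any((p <= 0) | (p > 1)):
        raise ConfigError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    passing = np.flatnonzero(sorted_p <= (np.arange(1, m + 1) * q / m))
    if passing.size == 0:
        return BHResult(q=q, cutoff=None)
    cutoff = float(sorted_p[passing[-1]])
    rejected = [nm for pv, nm in pairs if pv <= cutoff]
    return BHResult(q=q, cutoff=cutoff, rejected=rejected)


def welch_onesided(measures_a, measures_b) -> float:
    """One-sided two-sample t-test with unequal variances (Welch), H1:
    mean(b) > mean(a).

    Degenerate zero-variance inputs resolve by sign: p = 0 if mean(b) >
    mean(a), 1 if smaller, 0.5 if equal.
    """
    a = np.asarray(measures_a, dtype=np.float64)
    b = np.asarray(measures_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ConfigError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if b.mean() > a.mean():
            return 0.0
        if b.mean() < a.mean():
            return 1.0
        return 0.5
    return float(stats.ttest_ind(b, a, equal_var=False, alternative="greater").pvalue)


def run_cv(images, attrs, plan: CVPlan, input_spec, targets=None, q: float = 0.05):
    """Full CV protocol: refit features + ridge per cell, AUC on held-out rows.

    For every (repeat, fold) cell the input set (embedding backends, SVD
    reduction, ...) is fitted on training rows only, one ridge model is
    fitted per target variable, held-out images are scored, and a
    tie-aware AUC is recorded.  Cells where a variable has a single class
    in train or test are skipped for that variable (its k shrinks).

    Returns {variable: AUCResult} with 2SE and BH(q) flags set.
    """
    from .predict import fit_auto_ridge, predict_scores  # local: avoid cycle

    if targets is None:
        targets = list(attrs.names)
    tidx = []
    for t in targets:
        if t not in attrs.names:
            raise ConfigError(f"unknown target variable '{t}'")
        tidx.append(attrs.names.index(t))

    measures = {t: [] for t in targets}
    for repeat, fold in plan.cells():
        train, test = plan.split_rows(attrs.individual_id, repeat, fold)
        try:
            input_spec.fit(images, attrs, train)
            F_tr = input_spec.transform(images, attrs, train)
            F_te = input_spec.transform(images, attrs, test)
        except Exception as exc:
            raise RuntimeError(
                f"feature fit failed at repeat={repeat} fold={fold}: {exc}"
            ) from exc
        for t, j in zip(targets, tidx):
            y_tr = attrs.y[train, j]
            y_te = attrs.y[test, j]
            try:
                model = fit_auto_ridge(F_tr, y_tr)
                auc = compute_auc(predict_scores(model, F_te), y_te)
            except Exception as exc:
                raise RuntimeError(
                    f"fit failed at repeat={repeat} fold={fold} variable={t}: {exc}"
                ) from exc
            if auc is not None:
                measures[t].append(auc)

    results = {}
    for t in targets:
        arr = np.asarray(measures[t], dtype=np.float64)
        summary = summarize_auc(arr)
        if summary is None:
            results[t] = AUCResult(name=t, measures=arr)
            continue
        mean, se, p = summary
        results[t] = AUCResult(
            name=t,
            measures=arr,
            mean=mean,
            se=se,
            p_value=p,
            two_se_significant=two_se_select(mean, se),
        )
    bh = bh_select(
        [results[t].p_value for t in targets], q=q, names=targets
    )
    rejected = set(bh.rejected)
    for t in targets:
        if results[t].p_value is not None:
            results[t].bh_significant = t in rejected
    return results


def percent_increase(reference: float, new: float) -> float:
    """Relative increase in percent, e.g. 92 -> 127 is ~38%."""
    if reference == 0:
        raise ConfigError("reference count is zero")
    return 100.0 * (new - reference) / reference


def count_significant(nested_results: dict, q: float = 0.05) -> pd.DataFrame:
    """BH(q)-significant variable counts per input set, with % increases
    relative to the first (reference) set and the mean AUC per set."""
    rows = []
    ref = None
    for level, results in nested_results.items():
        ps = [r.p_value for r in results.values()]
        names = list(results.keys())
        n_sig = bh_select(ps, q=q, names=names).n_rejected
        means = [r.mean for r in results.values() if r.mean is not None]
        if ref is None:
            ref = n_sig
        rows.append(
            {
                "input_set": level,
                "n_significant": n_sig,
                "pct_increase_vs_reference": percent_increase(ref, n_sig)
                if ref
                else np.nan,
                "mean_auc": float(np.mean(means)) if means else np.nan,
            }
        )
    return pd.DataFrame(rows)


def ranking_table(results: dict) -> pd.DataFrame:
    """Per-variable ranking table sorted in increasing order of p-values."""
    rows = []
    for r in results.values():
        rows.append(
            {
                "variable": r.name,
                "k": r.k,
                "mean_auc": r.mean,
                "se": r.se,
                "p_value": r.p_value,
                "two_se_significant": r.two_se_significant,
                "bh_significant": r.bh_significant,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        "p_value", kind="stable", na_position="last", ignore_index=True
    )
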