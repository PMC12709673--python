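"""Cross-validated, stratum- and target-resolved evaluation with statistics.

Models are assessed by 10-fold cross-validation (9:1 split) repeated with
two independent seeds.  Metrics are F1 and area under the precision-recall
curve (average precision), chosen for robustness to the heavy class
imbalance of binding data, and are reported overall (micro over all
variant x target cells, with the macro alternative alongside), per
k-binding stratum, and per target.

The statistical battery mirrors the comparisons made on these metric
tables: Kruskal-Wallis with the epsilon-squared effect size H/(n-1), Dunn's
post-hoc test with Benjamini-Hochberg FDR correction, Mann-Whitney U,
Wilcoxon signed-rank and one-sample t tests, plus per-target logistic
regression and label-permutation baselines.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from statsmodels.stats.multitest import multipletests

from .classifier import ModelConfig, TrainedModel, make_xy, train
from .sequence_space import EmbeddingScheme, get_scheme

RESULT_COLUMNS = ("scheme", "model", "seed", "fold", "stratum", "target", "f1", "auprc")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def f1_score(true_bits: np.ndarray, predicted_bits: np.ndarray) -> float:
    """F1 = 2TP/(2TP+FP+FN) over flattened binary arrays.

    NaN (missing) when there are neither true nor predicted positives, so an
    unevaluable stratum is never reported as zero performance.
    """
    t = np.asarray(true_bits, dtype=bool).ravel()
    p = np.asarray(predicted_bits, dtype=bool).ravel()
    tp = np.sum(t & p)
    denom = t.sum() + p.sum()  # equals TP+FN + TP+FP
    if denom == 0:
        return np.nan
    return float(2.0 * tp / denom)


def auprc(true_bits: np.ndarray, scores: np.ndarray) -> float:
    """Step-wise average precision (no interpolation); NaN without positives."""
    t = np.asarray(true_bits, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if t.sum() == 0:
        return np.nan
    return float(average_precision_score(t, s))


def _metric_rows(
    y: np.ndarray,
    scores: np.ndarray,
    k: np.ndarray,
    targets: Sequence[str],
    threshold: float = 0.5,
) -> List[Dict]:
    bits = scores >= threshold
    rows: List[Dict] = [
        {"stratum": "all", "target": "all", "f1": f1_score(y, bits), "auprc": auprc(y, scores)}
    ]
    per_t_f1 = []
    per_t_ap = []
    for ti, t in enumerate(targets):
        f1t = f1_score(y[:, ti], bits[:, ti])
        apt = auprc(y[:, ti], scores[:, ti])
        per_t_f1.append(f1t)
        per_t_ap.append(apt)
        rows.append({"stratum": "all", "target": t, "f1": f1t, "auprc": apt})
    rows.append(
        {
            "stratum": "all",
            "target": "all_macro",
            "f1": float(np.nanmean(per_t_f1)) if per_t_f1 else np.nan,
            "auprc": float(np.nanmean(per_t_ap)) if per_t_ap else np.nan,
        }
    )
    for kk in sorted(np.unique(k)):
        m = k == kk
        rows.append(
            {
                "stratum": str(int(kk)),
                "target": "all",
                "f1": f1_score(y[m], bits[m]),
                "auprc": auprc(y[m], scores[m]),
            }
        )
    return rows


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def assign_folds(k: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """k-stratified fold assignment: a partition of rows into n_folds folds.

    Within each stratum, rows are shuffled and dealt round-robin from a
    random starting fold, so strata are spread as evenly as integer counts
    allow and every row lands in exactly one fold.
    """
    k = np.asarray(k)
    folds = np.empty(len(k), dtype=int)
    for kk in np.unique(k):
        idx = np.flatnonzero(k == kk)
        idx = rng.permutation(idx)
        start = int(rng.integers(n_folds))
        folds[idx] = (start + np.arange(len(idx))) % n_folds
    return folds


# ---------------------------------------------------------------------------
# model runners (MLP / logistic / permuted-label MLP)
# ---------------------------------------------------------------------------

def _fit_predict_mlp(Xtr, ytr, ktr, Xte, config, seed) -> np.ndarray:
    cfg = ModelConfig(**{**config.to_dict(), "seed": seed})
    model = train(Xtr, ytr, ktr, cfg)
    return model.predict(Xte)


def _fit_predict_logistic(Xtr, ytr, ktr, Xte, config, seed) -> np.ndarray:
    del ktr
    scores = np.zeros((len(Xte), ytr.shape[1]))
    for ti in range(ytr.shape[1]):
        col = ytr[:, ti]
        if col.min() == col.max():  # degenerate single-class training fold
            scores[:, ti] = float(col.max())
            continue
        clf = LogisticRegression(max_iter=1000, random_state=seed)
        clf.fit(Xtr, col)
        scores[:, ti] = clf.predict_proba(Xte)[:, 1]
    return scores


def _fit_predict_permuted(Xtr, ytr, ktr, Xte, config, seed) -> np.ndarray:
    rng = np.random.default_rng(seed + 1_000_003)
    perm = rng.permutation(len(ytr))  # break sequence-label pairing, keep label multiset
    yperm = ytr[perm]
    kperm = yperm.sum(axis=1).astype(int)
    return _fit_predict_mlp(Xtr, yperm, kperm, Xte, config, seed)


_RUNNERS = {
    "mlp": _fit_predict_mlp,
    "logistic": _fit_predict_logistic,
    "permuted": _fit_predict_permuted,
}


def cross_validate(
    profiles: pd.DataFrame,
    targets: Sequence[str],
    scheme: EmbeddingScheme | str,
    config: ModelConfig,
    n_folds: int = 10,
    n_seed_reps: int = 2,
    model: str = "mlp",
    base_seed: int = 0,
    sequence_column: str | None = None,
    fold_assignments: Mapping[int, np.ndarray] | None = None,
    folds_to_run: Sequence[int] | None = None,
) -> pd.DataFrame:
    """k-stratified cross-validation returning a tidy metric table.

    One row per (seed replicate, fold, stratum, target) cell with F1 and
    AUPRC on the held-out fold; strata/targets without evaluable rows are
    recorded as NaN, not zero.  ``fold_assignments`` (seed -> per-row fold
    ids) lets callers reuse identical partitions across models and masks for
    paired comparisons; ``folds_to_run`` restricts evaluation to a subset of
    the partition's folds (a cheaper but identically-split protocol).
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    runner = _RUNNERS[model]
    rows: List[Dict] = []
    for rep in range(n_seed_reps):
        seed = base_seed + rep
        if fold_assignments is not None:
            folds = np.asarray(fold_assignments[seed])
        else:
            folds = assign_folds(
                profiles["k"].to_numpy(), n_folds, np.random.default_rng(seed)
            )
        for f in folds_to_run if folds_to_run is not None else range(n_folds):
            tr = profiles.loc[folds != f]
            te = profiles.loc[folds == f]
            Xtr, ytr, ktr = make_xy(tr, targets, scheme, sequence_column)
            Xte, yte, kte = make_xy(te, targets, scheme, sequence_column)
            scores = runner(Xtr, ytr, ktr, Xte, config, seed)
            for cell in _metric_rows(yte, scores, kte, targets):
                rows.append(
                    {"scheme": scheme.name, "model": model, "seed": seed, "fold": f, **cell}
                )
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def logistic_baseline(
    profiles: pd.DataFrame,
    targets: Sequence[str],
    scheme: EmbeddingScheme | str = "BLOSUM50",
    config: ModelConfig | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Per-target logistic-regression baseline on the same folds as the MLP."""
    return cross_validate(
        profiles, targets, scheme, config or ModelConfig(), model="logistic", **kwargs
    )


def permutation_baseline(
    profiles: pd.DataFrame,
    targets: Sequence[str],
    scheme: EmbeddingScheme | str,
    config: ModelConfig,
    **kwargs,
) -> pd.DataFrame:
    """Chance-level control: labels permuted within each training fold only.

    Test folds are left intact, so metrics reflect what an uninformative
    model of the same capacity and sampling scheme achieves.
    """
    return cross_validate(
        profiles, targets, scheme, config, model="permuted", **kwargs
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    pvalue: float
    effect_size: float | None = None
    detail: pd.DataFrame | None = field(default=None, compare=False)


def kruskal_wallis_epsilon(groups: Sequence[Sequence[float]]) -> StatResult:
    """Kruskal-Wallis H (tie-corrected) with epsilon-squared = H/(n-1).

    Epsilon-squared is the rank-based proportion of variance explained by
    group membership, in [0, 1].  With all observations identical H = 0 and
    the p-value is 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n = sum(len(g) for g in groups)
    if n < 2:
        raise ValueError("need at least two observations")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return StatResult("kruskal-wallis", 0.0, 1.0, 0.0)
    H, p = stats.kruskal(*groups)
    return StatResult("kruskal-wallis", float(H), float(p), float(H / (n - 1)))


def dunn_posthoc_fdr(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Dunn's pairwise z tests after Kruskal-Wallis, BH-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)).  Returns one row per
    unordered pair with z, two-sided p and Benjamini-Hochberg q.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    i0 = 0
    for g in groups:
        mean_ranks.append(ranks[i0 : i0 + len(g)].mean())
        i0 += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(base_var * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "pvalue": p})
    out = pd.DataFrame(rows)
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def paired_and_unpaired_tests(
    a: Sequence[float],
    b: Sequence[float] | None = None,
    kind: str = "mann_whitney",
    alternative: str = "two-sided",
    popmean: float = 0.0,
) -> StatResult:
    """Mann-Whitney U, Wilcoxon signed-rank, or one-sample t.

    Wilcoxon with all-zero differences is degenerate and reported as p = 1.
    """
    a = np.asarray(a, dtype=float)
    if kind == "mann_whitney":
        if b is None:
            raise ValueError("mann_whitney requires two samples")
        U, p = stats.mannwhitneyu(a, np.asarray(b, float), alternative=alternative)
        return StatResult("mann-whitney-u", float(U), float(p))
    if kind == "wilcoxon_signed_rank":
        if b is None:
            raise ValueError("wilcoxon requires two paired samples")
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.all(d == 0):
            return StatResult("wilcoxon-signed-rank", 0.0, 1.0)
        W, p = stats.wilcoxon(a, b, alternative=alternative)
        return StatResult("wilcoxon-signed-rank", float(W), float(p))
    if kind == "one_sample_t":
        res = stats.ttest_1samp(a, popmean, alternative=alternative)
        return StatResult("one-sample-t", float(res.statistic), float(res.pvalue))
    raise ValueError(f"unknown test kind {kind!r}")


def sign_test(wins: int, trials: int, alternative: str = "greater") -> StatResult:
    """Exact binomial sign test against P(win) = 1/2."""
    res = stats.binomtest(wins, trials, 0.5, alternative=alternative)
    return StatResult("sign-test", float(wins), float(res.pvalue))
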