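"""Model assessment for presence/background suitability models.

Covers ROC/AUC by the Mann-Whitney rank statistic, seeded train/test splits
and k-fold partitions, percent contribution (training-gain attribution),
permutation importance (AUC drop), jackknife single-variable /
leave-one-variable-out gains, marginal response curves and optimal-range
extraction at a suitability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grid import OccurrenceSet

__all__ = [
    "roc_auc",
    "split_data",
    "cross_validate",
    "percent_contribution",
    "permutation_importance",
    "jackknife_gains",
    "response_curve",
    "optimal_range",
    "EvaluationReport",
    "evaluate",
]


def roc_auc(presence_scores, background_scores) -> float:
    """AUC = P(presence score > background score) + 0.5 P(tie).

    Computed from midranks (the Mann-Whitney U statistic), so ties
    contribute half and any strictly monotone transform of the scores leaves
    the value unchanged.
    """
    pos = np.asarray(presence_scores, dtype=float).ravel()
    neg = np.asarray(background_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def split_data(occurrences: OccurrenceSet, test_fraction: float = 0.25, seed=None):
    """Random disjoint train/test split; test size = round-half-up(n * fraction)."""
    n = len(occurrences)
    n_test = int(np.floor(n * test_fraction + 0.5))
    if n_test < 1 or n_test >= n:
        raise ValueError(f"test fraction {test_fraction} leaves no usable split of {n} points")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return occurrences.take(order[n_test:]), occurrences.take(order[:n_test])


def cross_validate(occurrences: OccurrenceSet, k: int = 10, seed=None):
    """Seeded k-fold partition; returns [(train, test), ...] with fold sizes within 1."""
    n = len(occurrences)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} points")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    out = []
    for i in range(k):
        test_idx = folds[i]
        train_idx = np.concatenate([folds[j] for j in range(k) if j != i])
        out.append((occurrences.take(train_idx), occurrences.take(test_idx)))
    return out


# ---------------------------------------------------------------------------
# Variable importance

def _variable_shares(results, per_feature: np.ndarray) -> pd.Series:
    """Aggregate a per-feature vector to variables; products split equally."""
    shares = {v: 0.0 for v in results.model.var_names}
    for d, val in zip(results.model.defs, per_feature):
        for v in d.variables:
            shares[v] += val / len(d.variables)
    return pd.Series(shares)


def percent_contribution(results) -> pd.Series:
    """Percent contribution: positive training-gain increments credited to the
    updated feature's source variable(s), normalised to sum 100."""
    s = _variable_shares(results, results.trace)
    total = s.sum()
    if total <= 0:
        import warnings

        warnings.warn("zero total training gain; contributions are all zero")
        return s * 0.0
    return 100.0 * s / total


def permutation_importance(results, seed=None, n_repeats: int = 1) -> pd.Series:
    """Permutation importance: normalised training-AUC drop per variable.

    Each variable's raw column is permuted jointly across the presence and
    background rows, features are re-evaluated, and the drop in training AUC
    (floored at 0) is averaged over repeats and scaled to sum 100.
    """
    model = results.model
    rng = np.random.default_rng(seed)
    base_auc = roc_auc(
        results.linear_predictor(model.presence, clamp=False),
        results.linear_predictor(model.background, clamp=False),
    )
    m = model.presence.shape[0]
    stacked = np.vstack([model.presence, model.background])
    drops = {}
    for j, name in enumerate(model.var_names):
        acc = 0.0
        for _ in range(n_repeats):
            perm = stacked.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            auc = roc_auc(
                results.linear_predictor(perm[:m], clamp=False),
                results.linear_predictor(perm[m:], clamp=False),
            )
            acc += max(base_auc - auc, 0.0)
        drops[name] = acc / n_repeats
    s = pd.Series(drops)
    total = s.sum()
    return s * 0.0 if total <= 0 else 100.0 * s / total


def jackknife_gains(model, rm: float = 1.0, max_iter: int = 200, tol: float = 1e-4) -> pd.DataFrame:
    """Single-variable ("with only") and leave-one-out ("without") training gains.

    Refits the model for each variable alone and each variable excluded,
    using the same feature classes, and reports the regularized training
    gain of each fit next to the full-model gain.
    """
    from .model import MaxEnt

    names = model.var_names
    full = model.fit(rm=rm, max_iter=max_iter, tol=tol)
    rows = []
    for i, name in enumerate(names):
        only = MaxEnt(
            model.presence[:, [i]],
            model.background[:, [i]],
            [name],
            fc=model.fc,
            n_knots=model.n_knots,
        ).fit(rm=rm, max_iter=max_iter, tol=tol)
        if len(names) > 1:
            rest = [j for j in range(len(names)) if j != i]
            without = MaxEnt(
                model.presence[:, rest],
                model.background[:, rest],
                [names[j] for j in rest],
                fc=model.fc,
                n_knots=model.n_knots,
            ).fit(rm=rm, max_iter=max_iter, tol=tol)
            wo_gain = without.gain
        else:
            wo_gain = 0.0  # uniform model
        rows.append(
            {
                "variable": name,
                "gain_with_only": only.gain,
                "gain_without": wo_gain,
                "gain_full": full.gain,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Response curves

def response_curve(results, variable: str, n_grid: int = 100, output: str = "cloglog"):
    """Marginal response: sweep one variable over its training range with all
    others held at their background means.  Returns (x_grid, prediction)."""
    model = results.model
    j = model.var_names.index(variable)
    x = np.linspace(model.clamp_lo[j], model.clamp_hi[j], n_grid)
    base = model.background.mean(axis=0)
    Xg = np.tile(base, (n_grid, 1))
    Xg[:, j] = x
    return x, results.predict(Xg, output=output, clamp=True)


def optimal_range(x: np.ndarray, y: np.ndarray, threshold: float = 0.6):
    """Maximal sub-intervals of a response curve with prediction >= threshold.

    Returns ``(intervals, x_argmax)`` where intervals is a list of
    (lo, hi) pairs in the variable's units (empty if the curve never reaches
    the threshold).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    above = y >= threshold
    intervals = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            intervals.append((float(x[start]), float(x[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(x[start]), float(x[-1])))
    return intervals, float(x[int(np.argmax(y))])


# ---------------------------------------------------------------------------
# Combined report

@dataclass
class EvaluationReport:
    train_auc: float
    test_auc: float
    contribution: pd.Series
    importance: pd.Series
    jackknife: pd.DataFrame
    optimal_ranges: dict

    def summary(self) -> str:
        lines = [
            "Model evaluation",
            "=" * 40,
            f"training AUC: {self.train_auc:.4f}",
            f"test AUC:     {self.test_auc:.4f}",
            "",
            "percent contribution / permutation importance:",
        ]
        for v in self.contribution.index:
            lines.append(
                f"  {v:<12s} {self.contribution[v]:6.1f}%   {self.importance[v]:6.1f}%"
            )
        lines.append("")
        lines.append("jackknife training gains (with only / without / full):")
        for _, r in self.jackknife.iterrows():
            lines.append(
                f"  {r.variable:<12s} {r.gain_with_only:7.4f}  {r.gain_without:7.4f}"
                f"  {r.gain_full:7.4f}"
            )
        if self.optimal_ranges:
            lines.append("")
            lines.append("optimal ranges (suitability >= threshold):")
            for v, (ivs, argmax) in self.optimal_ranges.items():
                span = ", ".join(f"[{a:.3g}, {b:.3g}]" for a, b in ivs) or "none"
                lines.append(f"  {v:<12s} {span}  (peak at {argmax:.3g})")
        return "\n".join(lines)


def evaluate(
    stack,
    occurrences: OccurrenceSet,
    fc: str = "LQHPT",
    rm: float = 1.0,
    test_fraction: float = 0.25,
    n_background: int = 10_000,
    n_knots: int = 50,
    max_iter: int = 500,
    range_threshold: float = 0.6,
    jackknife: bool = True,
    seed=None,
) -> tuple:
    """Fit on a seeded 75/25-style split and assemble an EvaluationReport.

    Returns ``(results, report)`` so the fitted model can be reused for
    projection.
    """
    from .grid import extract_values
    from .model import MaxEnt

    train_occ, test_occ = split_data(occurrences, test_fraction=test_fraction, seed=seed)
    model = MaxEnt.from_stack(
        stack, train_occ, fc=fc, n_knots=n_knots, n_background=n_background, seed=seed
    )
    results = model.fit(rm=rm, max_iter=max_iter)
    Xt, valid = extract_values(stack, test_occ.points)
    sb = results.predict(model.background, output="raw")
    train_auc = roc_auc(results.predict(model.presence, output="raw"), sb)
    test_auc = roc_auc(results.predict(Xt[valid], output="raw"), sb)
    contribution = percent_contribution(results)
    importance = permutation_importance(results, seed=seed)
    jk = (
        jackknife_gains(model, rm=rm)
        if jackknife
        else pd.DataFrame(columns=["variable", "gain_with_only", "gain_without", "gain_full"])
    )
    ranges = {}
    for v in model.var_names:
        x, y = response_curve(results, v)
        ranges[v] = optimal_range(x, y, threshold=range_threshold)
    report = EvaluationReport(
        train_auc=train_auc,
        test_auc=test_auc,
        contribution=contribution,
        importance=importance,
        jackknife=jk,
        optimal_ranges=ranges,
    )
    return results, report
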