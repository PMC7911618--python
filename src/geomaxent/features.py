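"""Feature transforms for the maximum-entropy model.

Feature classes follow the standard presence/background vocabulary:

* ``L`` linear — the variable itself;
* ``Q`` quadratic — its square;
* ``P`` product — all unordered pairwise products;
* ``H`` hinge — forward ``clip((x-k)/(max-k), 0, 1)`` and reverse
  ``clip((k-x)/(k-min), 0, 1)`` ramps at K knots per variable;
* ``T`` threshold — step indicators ``x > k`` at the same knots.

Knots sit at equispaced quantiles of the training values; every feature is
min-max normalised to [0, 1] on the training sample so that the L1 penalty
acts on a common scale.  Features that are constant on the training sample
are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureDefinition", "build_features", "evaluate_features", "FEATURE_CLASSES"]

FEATURE_CLASSES = "LQHPT"


@dataclass(frozen=True)
class FeatureDefinition:
    kind: str  # linear | quadratic | product | hinge | threshold
    variables: tuple[str, ...]
    var_idx: tuple[int, ...]
    knot: float | None = None
    direction: str | None = None  # hinge only: forward | reverse
    lo: float = 0.0  # normalization bounds of the raw feature on training data
    hi: float = 1.0

    @property
    def label(self) -> str:
        v = "*".join(self.variables)
        if self.kind == "linear":
            return v
        if self.kind == "quadratic":
            return f"{v}^2"
        if self.kind == "product":
            return v
        if self.kind == "hinge":
            tag = "hinge" if self.direction == "forward" else "hinge'"
            return f"{tag}({v}@{self.knot:.4g})"
        return f"thresh({v}>{self.knot:.4g})"

    def raw(self, X: np.ndarray) -> np.ndarray:
        """Un-normalised feature value from a raw sample matrix."""
        i = self.var_idx[0]
        if self.kind == "linear":
            return X[:, i]
        if self.kind == "quadratic":
            return X[:, i] ** 2
        if self.kind == "product":
            return X[:, i] * X[:, self.var_idx[1]]
        if self.kind == "hinge":
            if self.direction == "forward":
                return np.clip((X[:, i] - self.knot) / (self.hi - self.knot), 0.0, 1.0)
            return np.clip((self.knot - X[:, i]) / (self.knot - self.lo), 0.0, 1.0)
        if self.kind == "threshold":
            return (X[:, i] > self.knot).astype(float)
        raise ValueError(f"unknown feature kind {self.kind!r}")

    def __call__(self, X: np.ndarray) -> np.ndarray:
        """Normalised feature value in [0, 1] on training data."""
        f = self.raw(X)
        if self.kind in ("hinge", "threshold"):
            return f  # already [0, 1] by construction
        return (f - self.lo) / (self.hi - self.lo)


def _knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Interior equispaced-quantile knots (training range endpoints excluded)."""
    probs = (np.arange(n_knots) + 1.0) / (n_knots + 1.0)
    return np.quantile(x, probs)


def build_features(
    X_train: np.ndarray,
    var_names: list[str],
    fc: str = "LQHPT",
    n_knots: int = 50,
) -> list[FeatureDefinition]:
    """Construct feature definitions of the requested classes from training data.

    ``X_train`` is the raw (n_samples, n_variables) training matrix used for
    normalization bounds and knot placement (conventionally presences and
    background together).
    """
    fc = fc.upper()
    for ch in fc:
        if ch not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {ch!r}; allowed: {FEATURE_CLASSES}")
    X_train = np.asarray(X_train, dtype=float)
    p = X_train.shape[1]
    if p != len(var_names):
        raise ValueError("var_names length must match number of columns")

    defs: list[FeatureDefinition] = []

    def add(kind, idx, knot=None, direction=None):
        names = tuple(var_names[i] for i in idx)
        if kind in ("hinge", "threshold"):
            lo = float(np.min(X_train[:, idx[0]]))
            hi = float(np.max(X_train[:, idx[0]]))
        else:
            proto = FeatureDefinition(kind, names, idx, knot, direction)
            raw = proto.raw(X_train)
            lo, hi = float(np.min(raw)), float(np.max(raw))
        if hi <= lo:
            return  # constant on training data: uninformative
        if kind == "hinge":
            if direction == "forward" and not knot < hi:
                return
            if direction == "reverse" and not knot > lo:
                return
        defs.append(FeatureDefinition(kind, names, idx, knot, direction, lo, hi))

    if "L" in fc:
        for i in range(p):
            add("linear", (i,))
    if "Q" in fc:
        for i in range(p):
            add("quadratic", (i,))
    if "P" in fc:
        for i in range(p):
            for j in range(i + 1, p):
                add("product", (i, j))
    if "H" in fc:
        for i in range(p):
            for k in np.unique(_knots(X_train[:, i], n_knots)):
                add("hinge", (i,), knot=float(k), direction="forward")
                add("hinge", (i,), knot=float(k), direction="reverse")
    if "T" in fc:
        for i in range(p):
            for k in np.unique(_knots(X_train[:, i], n_knots)):
                add("threshold", (i,), knot=float(k))
    return defs


def evaluate_features(defs: list[FeatureDefinition], X: np.ndarray) -> np.ndarray:
    """(n_samples, n_features) normalised feature matrix for raw samples X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not defs:
        return np.empty((X.shape[0], 0))
    return np.column_stack([d(X) for d in defs])
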