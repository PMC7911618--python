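"""Presence/background maximum-entropy species distribution model.

The model is the Gibbs distribution over the background landscape

    p_lambda(x)  proportional to  exp( sum_j lambda_j f_j(x) )

whose feature weights maximise the L1-penalised log-likelihood of the
presence sample:

    l(lambda) = mean_presence[ eta(x) ] - log Z(lambda)
                - RM * sum_j beta_j |lambda_j|,

with Z the partition function over the background sample and beta_j the
class-default regularization for feature j (piecewise-linear in the presence
count, scaled by the feature's presence standard deviation / sqrt(m)).  At
the optimum the KKT conditions pin every feature's model expectation within
RM*beta_j of its empirical presence mean — the classic "relaxed
maximum-entropy" constraint set.

Fitting is cyclic coordinate descent with exact soft-threshold proximal
Newton steps and a monotone line search; usage follows the model/results
convention:

    model = MaxEnt.from_stack(stack, occurrences, fc="LQHPT", seed=0)
    res = model.fit(rm=1.0)
    res.summary()
    suit = res.project(stack)          # cloglog suitability map
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .features import FeatureDefinition, build_features, evaluate_features
from .grid import OccurrenceSet, RasterLayer, RasterStack, extract_values

__all__ = [
    "MaxEnt",
    "MaxEntResults",
    "SuitabilityMap",
    "sample_background",
    "train",
    "tune",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

# Published class-default regularization schedules: (presence counts, betas),
# interpolated linearly and clipped at the ends.
_BETA_TABLE = {
    "linear": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "product": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "hinge": ([0, 1], [0.5, 0.5]),
    "threshold": ([0, 100], [2.0, 1.0]),
}


def default_betas(defs: list[FeatureDefinition], Fp: np.ndarray) -> np.ndarray:
    """Per-feature L1 penalty weights for a presence feature matrix Fp."""
    m = Fp.shape[0]
    sd = Fp.std(axis=0)
    betas = np.empty(len(defs))
    for j, d in enumerate(defs):
        xs, ys = _BETA_TABLE[d.kind]
        base = float(np.interp(m, xs, ys))
        b = base * sd[j] / np.sqrt(m)
        # floors keep near-constant hinge/threshold features from exploding
        if d.kind == "hinge":
            b = max(b, 0.5 / np.sqrt(m))
        elif d.kind == "threshold":
            b = max(b, 1.0 / np.sqrt(m))
        else:
            b = max(b, 1e-4)
        betas[j] = b
    return betas


@dataclass
class SuitabilityMap:
    """Raster of model output under a named transform (raw/logistic/cloglog)."""

    layer: RasterLayer
    transform: str


# ---------------------------------------------------------------------------
# Background sampling

def sample_background(stack: RasterStack, n: int = 10_000, seed=None):
    """Uniform sample of valid cells, without replacement.

    Returns ``(X, rows, cols)``.  If fewer than ``n`` valid cells exist, all
    of them are returned (with a log notice).
    """
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    n_valid = rows.size
    if n_valid == 0:
        raise ValueError("no valid cells to sample background from")
    rng = np.random.default_rng(seed)
    if n >= n_valid:
        if n > n_valid:
            log.info("background capped at %d valid cells (requested %d)", n_valid, n)
        idx = np.arange(n_valid)
    else:
        idx = rng.choice(n_valid, size=n, replace=False)
    r, c = rows[idx], cols[idx]
    X = np.column_stack([lay.values[r, c] for lay in stack.layers])
    return X, r, c


# ---------------------------------------------------------------------------
# Training

def _penalized_gain(lam, pbar, logZ, n_bg, betas, rm):
    return float(pbar @ lam - (logZ - np.log(n_bg)) - rm * np.abs(lam) @ betas)


def train(
    Fp: np.ndarray,
    Fb: np.ndarray,
    rm: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-5,
    betas: np.ndarray | None = None,
    defs: list[FeatureDefinition] | None = None,
):
    """Fit weights by cyclic coordinate descent with soft-threshold updates.

    ``Fp``/``Fb`` are presence/background feature matrices sharing columns.
    ``betas`` overrides the class-default penalties (all features are treated
    as linear-class when ``defs`` is omitted).  Iteration stops when the KKT
    violation max_j( |pbar_j - E_j| - RM*beta_j )_+ (sign-adjusted for active
    features) drops below ``tol``, or after ``max_iter`` sweeps.

    Returns a dict with the fitted state (weights, logZ, gain, trace, ...);
    :meth:`MaxEnt.fit` wraps it into :class:`MaxEntResults`.
    """
    Fp = np.atleast_2d(np.asarray(Fp, dtype=float))
    Fb = np.atleast_2d(np.asarray(Fb, dtype=float))
    if Fp.shape[1] != Fb.shape[1]:
        raise ValueError("presence and background feature matrices differ in columns")
    if not (np.all(np.isfinite(Fp)) and np.all(np.isfinite(Fb))):
        raise ValueError("non-finite feature values")
    m, J = Fp.shape
    n_bg = Fb.shape[0]
    if m < 2:
        raise ValueError("need at least 2 presence samples")
    if betas is None:
        if defs is None:
            defs_eff = [
                FeatureDefinition("linear", (f"f{j}",), (j,), lo=0.0, hi=1.0) for j in range(J)
            ]
        else:
            defs_eff = defs
        betas = default_betas(defs_eff, Fp)
    betas = np.asarray(betas, dtype=float)

    pbar = Fp.mean(axis=0)
    lam = np.zeros(J)
    eta = np.zeros(n_bg)
    logZ = np.log(n_bg)
    w = np.full(n_bg, 1.0 / n_bg)
    gain = 0.0
    trace = np.zeros(J)  # positive penalized-gain increments per feature
    reg = rm * betas

    n_iter = 0
    converged = False
    kkt = np.inf
    working = np.arange(J)
    for sweep in range(max_iter):
        n_iter = sweep + 1
        for j in working:
            fj = Fb[:, j]
            Ej = w @ fj
            g = pbar[j] - Ej
            h = max(w @ (fj * fj) - Ej * Ej, 1e-12)
            z = lam[j] + g / h
            target = np.sign(z) * max(abs(z) - reg[j] / h, 0.0)
            delta = target - lam[j]
            if abs(delta) < 1e-13:
                continue
            # monotone line search on the true penalized gain
            accepted = False
            for _ in range(40):
                lam_j_new = lam[j] + delta
                eta_t = eta + delta * fj
                logZ_t = logsumexp(eta_t)
                gain_t = (
                    gain
                    + pbar[j] * delta
                    - (logZ_t - logZ)
                    - reg[j] * (abs(lam_j_new) - abs(lam[j]))
                )
                if gain_t >= gain - 1e-12:
                    accepted = True
                    break
                delta *= 0.5
            if not accepted:
                continue
            trace[j] += max(gain_t - gain, 0.0)
            lam[j] = lam_j_new
            eta = eta_t
            logZ = logZ_t
            gain = gain_t
            w = np.exp(eta - logZ)
        # KKT check on the full gradient
        E = Fb.T @ w
        grad = pbar - E
        viol = np.where(
            lam != 0.0,
            np.abs(grad - reg * np.sign(lam)),
            np.maximum(np.abs(grad) - reg, 0.0),
        )
        kkt = float(viol.max()) if J else 0.0
        if kkt < tol:
            converged = True
            break
        # working set for the next sweep: active features + KKT violators
        working = np.flatnonzero((lam != 0.0) | (viol >= tol))

    entropy = float(-(w @ np.log(np.maximum(w, 1e-300))))
    return {
        "weights": lam,
        "betas": betas,
        "rm": rm,
        "logZ": float(logZ),
        "gain": float(gain),
        "entropy": entropy,
        "trace": trace,
        "n_iter": n_iter,
        "converged": converged,
        "kkt_violation": kkt,
        "raw_background": w,
    }


# ---------------------------------------------------------------------------
# Model / results

class MaxEnt:
    """Maximum-entropy presence/background model specification.

    Parameters
    ----------
    presence, background : (n, p) raw sample matrices over the same variables
    var_names : variable names (column order)
    fc : feature-class string, subset of "LQHPT"
    n_knots : hinge/threshold knots per variable per direction
    """

    def __init__(
        self,
        presence: np.ndarray,
        background: np.ndarray,
        var_names: list[str],
        fc: str = "LQHPT",
        n_knots: int = 50,
    ):
        self.presence = np.atleast_2d(np.asarray(presence, dtype=float))
        self.background = np.atleast_2d(np.asarray(background, dtype=float))
        if self.presence.shape[1] != self.background.shape[1]:
            raise ValueError("presence and background differ in variable count")
        self.var_names = list(var_names)
        self.fc = fc.upper()
        self.n_knots = n_knots
        X_train = np.vstack([self.presence, self.background])
        self.clamp_lo = X_train.min(axis=0)
        self.clamp_hi = X_train.max(axis=0)
        self.defs = build_features(X_train, self.var_names, self.fc, n_knots)
        self.Fp = evaluate_features(self.defs, self.presence)
        self.Fb = evaluate_features(self.defs, self.background)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_stack(
        cls,
        stack: RasterStack,
        occurrences: OccurrenceSet,
        fc: str = "LQHPT",
        n_knots: int = 50,
        n_background: int = 10_000,
        seed=None,
        dedupe: bool = True,
    ) -> "MaxEnt":
        """Build the model from rasters + occurrence points.

        Occurrences on nodata cells or outside the extent are dropped (with a
        log notice); duplicates within one cell collapse to a single record.
        Background is a uniform sample of valid cells.
        """
        row, col, inside = stack.spec.locate(occurrences.lon, occurrences.lat)
        X, valid = extract_values(stack, occurrences.points)
        n_drop = int((~valid).sum())
        if n_drop:
            log.info("dropped %d occurrence(s) outside the extent or on nodata", n_drop)
        row, col, X = row[valid], col[valid], X[valid]
        if dedupe:
            _, keep = np.unique(row * stack.spec.n_cols + col, return_index=True)
            keep = np.sort(keep)
            if keep.size < row.size:
                log.info("collapsed %d duplicate presence cell(s)", row.size - keep.size)
            X = X[keep]
        if X.shape[0] < 2:
            raise ValueError("fewer than 2 usable presence records")
        Xb, _, _ = sample_background(stack, n=n_background, seed=seed)
        return cls(X, Xb, stack.names, fc=fc, n_knots=n_knots)

    @property
    def n_presence(self) -> int:
        return self.Fp.shape[0]

    @property
    def n_background(self) -> int:
        return self.Fb.shape[0]

    def fit(self, rm: float = 1.0, max_iter: int = 500, tol: float = 1e-5) -> "MaxEntResults":
        state = train(self.Fp, self.Fb, rm=rm, max_iter=max_iter, tol=tol, defs=self.defs)
        if not state["converged"]:
            log.info(
                "stopped at max_iter=%d with KKT violation %.3g",
                max_iter,
                state["kkt_violation"],
            )
        return MaxEntResults(model=self, **state)


@dataclass
class MaxEntResults:
    """Fitted maximum-entropy model: weights, normalizer, diagnostics."""

    model: MaxEnt
    weights: np.ndarray
    betas: np.ndarray
    rm: float
    logZ: float
    gain: float
    entropy: float
    trace: np.ndarray
    n_iter: int
    converged: bool
    kkt_violation: float
    raw_background: np.ndarray = field(repr=False, default=None)

    # -- prediction -------------------------------------------------------
    def linear_predictor(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if clamp:
            X = np.clip(X, self.model.clamp_lo, self.model.clamp_hi)
        F = evaluate_features(self.model.defs, X)
        return F @ self.weights

    def predict(self, X: np.ndarray, output: str = "cloglog", clamp: bool = True) -> np.ndarray:
        """Predicted suitability for raw variable rows X.

        raw: exp(eta)/Z (sums to 1 over the training background);
        logistic: r e^H / (1 + r e^H);  cloglog: 1 - exp(-r e^H).
        """
        eta = self.linear_predictor(X, clamp=clamp)
        raw = np.exp(eta - self.logZ)
        if output == "raw":
            return raw
        s = raw * np.exp(self.entropy)
        if output == "logistic":
            return s / (1.0 + s)
        if output == "cloglog":
            return 1.0 - np.exp(-s)
        raise ValueError(f"unknown output transform {output!r}")

    def project(
        self, stack: RasterStack, output: str = "cloglog", clamp: bool = True
    ) -> SuitabilityMap:
        """Predict over every valid cell of a (scenario) stack."""
        sub = stack.subset(self.model.var_names)  # KeyError if a variable is missing
        X, rows, cols = sub.cell_table()
        pred = self.predict(X, output=output, clamp=clamp)
        vals = np.full(sub.spec.shape, np.nan)
        vals[rows, cols] = pred
        layer = RasterLayer(name=f"suitability_{output}", spec=sub.spec, values=vals)
        return SuitabilityMap(layer=layer, transform=output)

    # -- diagnostics ------------------------------------------------------
    def params_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [d.label for d in self.model.defs],
                "kind": [d.kind for d in self.model.defs],
                "weight": self.weights,
                "beta": self.betas,
            }
        )

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))

    def summary(self) -> str:
        lines = [
            "Maximum-entropy presence/background model",
            "=" * 45,
            f"presences: {self.model.n_presence}    background: {self.model.n_background}",
            f"feature classes: {self.model.fc}    features: {len(self.weights)}"
            f" (nonzero: {self.n_nonzero})",
            f"RM: {self.rm}    iterations: {self.n_iter}"
            f" ({'converged' if self.converged else 'max_iter reached'})",
            f"regularized training gain: {self.gain:.4f}",
            f"entropy of fitted background distribution: {self.entropy:.4f}",
            f"KKT violation: {self.kkt_violation:.2e}",
            "",
            "largest |weight| features:",
        ]
        tab = self.params_table()
        top = tab.reindex(tab.weight.abs().sort_values(ascending=False).index).head(10)
        for _, r in top.iterrows():
            lines.append(f"  {r.feature:<40s} {r.weight:+.4f}")
        return "\n".join(lines)

    # convenience delegations (implementations live in `evaluation`)
    def percent_contribution(self) -> pd.Series:
        from .evaluation import percent_contribution

        return percent_contribution(self)

    def permutation_importance(self, seed=None, n_repeats: int = 1) -> pd.Series:
        from .evaluation import permutation_importance

        return permutation_importance(self, seed=seed, n_repeats=n_repeats)

    def response_curve(self, variable: str, n_grid: int = 100, output: str = "cloglog"):
        from .evaluation import response_curve

        return response_curve(self, variable, n_grid=n_grid, output=output)

    def plot_response(self, variable: str, ax=None, **kw):
        """Marginal response curve plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        x, y = self.response_curve(variable, **kw)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(x, y)
        ax.set_xlabel(variable)
        ax.set_ylabel("suitability")
        return ax


# ---------------------------------------------------------------------------
# Hyperparameter sweep

DEFAULT_FCS = ("L", "LQ", "H", "LQH", "LQHP", "LQHPT")


def tune(
    stack: RasterStack,
    occurrences: OccurrenceSet,
    rm_grid=None,
    fcs=DEFAULT_FCS,
    test_fraction: float = 0.25,
    n_background: int = 10_000,
    n_knots: int = 50,
    max_iter: int = 500,
    seed=None,
) -> pd.DataFrame:
    """Fit every (RM, FC) combination on one fixed seeded split.

    Returns the ranking table (rm, fc, n_features, n_nonzero, gain,
    train_auc, test_auc); no combination is auto-selected.
    """
    from .evaluation import roc_auc, split_data

    if rm_grid is None:
        rm_grid = np.arange(0.5, 4.01, 0.5)
    train_occ, test_occ = split_data(occurrences, test_fraction=test_fraction, seed=seed)
    rows = []
    for fc in fcs:
        model = MaxEnt.from_stack(
            stack, train_occ, fc=fc, n_knots=n_knots, n_background=n_background, seed=seed
        )
        Xt, valid_t = extract_values(stack, test_occ.points)
        Xt = Xt[valid_t]
        for rm in rm_grid:
            res = model.fit(rm=float(rm), max_iter=max_iter)
            sp = res.predict(model.presence, output="raw")
            sb = res.predict(model.background, output="raw")
            st = res.predict(Xt, output="raw")
            rows.append(
                {
                    "rm": float(rm),
                    "fc": fc,
                    "n_features": len(res.weights),
                    "n_nonzero": res.n_nonzero,
                    "gain": res.gain,
                    "train_auc": roc_auc(sp, sb),
                    "test_auc": roc_auc(st, sb),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plain-text model serialization (a human-diffable lambdas-style file)

def save_model(res: MaxEntResults, path) -> None:
    m = res.model
    with open(path, "w") as fh:
        fh.write("# geomaxent model 1\n")
        fh.write(f"fc {m.fc}\n")
        fh.write(f"n_knots {m.n_knots}\n")
        fh.write(f"rm {res.rm!r}\n")
        fh.write(f"logZ {res.logZ!r}\n")
        fh.write(f"entropy {res.entropy!r}\n")
        fh.write(f"gain {res.gain!r}\n")
        fh.write(f"variables {','.join(m.var_names)}\n")
        fh.write("clamp_lo " + ",".join(repr(float(v)) for v in m.clamp_lo) + "\n")
        fh.write("clamp_hi " + ",".join(repr(float(v)) for v in m.clamp_hi) + "\n")
        fh.write("kind\tvar_idx\tknot\tdirection\tlo\thi\tweight\tbeta\n")
        for d, wgt, b in zip(m.defs, res.weights, res.betas):
            fh.write(
                f"{d.kind}\t{','.join(map(str, d.var_idx))}\t"
                f"{'' if d.knot is None else repr(float(d.knot))}\t{d.direction or ''}\t"
                f"{float(d.lo)!r}\t{float(d.hi)!r}\t{float(wgt)!r}\t{float(b)!r}\n"
            )


def load_model(path) -> MaxEntResults:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("# geomaxent model"):
        raise ValueError(f"{path}: not a geomaxent model file")
    head = {}
    i = 1
    while not lines[i].startswith("kind\t"):
        key, _, val = lines[i].partition(" ")
        head[key] = val
        i += 1
    var_names = head["variables"].split(",")
    defs, weights, betas = [], [], []
    for ln in lines[i + 1 :]:
        if not ln.strip():
            continue
        kind, idx_s, knot_s, direction, lo, hi, wgt, b = ln.split("\t")
        idx = tuple(int(v) for v in idx_s.split(","))
        defs.append(
            FeatureDefinition(
                kind,
                tuple(var_names[k] for k in idx),
                idx,
                None if knot_s == "" else float(knot_s),
                direction or None,
                float(lo),
                float(hi),
            )
        )
        weights.append(float(wgt))
        betas.append(float(b))

    model = MaxEnt.__new__(MaxEnt)
    model.var_names = var_names
    model.fc = head["fc"]
    model.n_knots = int(head["n_knots"])
    model.clamp_lo = np.array([float(v) for v in head["clamp_lo"].split(",")])
    model.clamp_hi = np.array([float(v) for v in head["clamp_hi"].split(",")])
    model.defs = defs
    model.presence = None
    model.background = None
    model.Fp = None
    model.Fb = None
    return MaxEntResults(
        model=model,
        weights=np.array(weights),
        betas=np.array(betas),
        rm=float(head["rm"]),
        logZ=float(head["logZ"]),
        gain=float(head["gain"]),
        entropy=float(head["entropy"]),
        trace=np.zeros(len(weights)),
        n_iter=0,
        converged=True,
        kkt_violation=np.nan,
        raw_background=None,
    )
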