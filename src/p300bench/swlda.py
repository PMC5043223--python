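"""Stepwise linear discriminant analysis (SWLDA).

The classical P300 classifier: ordinary least-squares regression of ±1 class
labels on a subset of features chosen by forward entry / backward removal
using partial-F significance tests.  Forward entry adds the out-of-model
feature with the smallest partial-F p-value when it is below ``p_enter``;
backward removal drops any in-model feature whose p-value exceeds
``p_remove``; iteration stops when neither step changes the model or
``max_features`` is reached.

The fit works on the centred Gram matrices ``X'X`` and ``X'y``, so screening
all candidate features at one step costs O(candidates × k²) instead of one
least-squares solve per candidate; the resulting weights are algebraically
identical to regressing y on the selected columns plus an intercept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = ["SWLDAModel", "fit_swlda", "score"]

_RIDGE_TOL = 1e-10  # relative tolerance below which a candidate is collinear


@dataclass
class SWLDAModel:
    """Selected feature indices, their weights, and the intercept."""

    selected: list[int]
    weights: np.ndarray
    intercept: float
    p_enter: float = 0.10
    p_remove: float = 0.15
    max_features: int = 60

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected feature indices must be unique")
        if len(self.weights) != len(self.selected):
            raise ValueError("weights length must equal |selected|")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "selected": list(map(int, self.selected)),
                "weights": self.weights.tolist(),
                "intercept": float(self.intercept),
                "p_enter": self.p_enter,
                "p_remove": self.p_remove,
                "max_features": self.max_features,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "SWLDAModel":
        if isinstance(doc, Path) or (isinstance(doc, str) and "\n" not in doc
                                     and doc.endswith(".json")):
            doc = Path(doc).read_text()
        d = json.loads(doc)
        return cls(d["selected"], np.asarray(d["weights"]), d["intercept"],
                   d["p_enter"], d["p_remove"], d["max_features"])


def fit_swlda(
    X: np.ndarray,
    y: np.ndarray,
    p_enter: float = 0.10,
    p_remove: float = 0.15,
    max_features: int = 60,
) -> SWLDAModel:
    """Fit an SWLDA discriminant to features ``X`` and ±1 labels ``y``.

    Raises ``ValueError`` when only one class is present.  A degenerate
    design (every feature with zero variance) yields an *empty* model with a
    warning, whose scores are the constant intercept.  Candidates that are
    numerically collinear with the current model are refused entry.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be items × features aligned with y")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two observations")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in y")
    if not (0 < p_enter <= 1 and 0 < p_remove <= 1 and p_enter <= p_remove):
        raise ValueError("require 0 < p_enter <= p_remove <= 1")

    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    G = Xc.T @ Xc
    g = Xc.T @ yc
    syy = float(yc @ yc)
    var = np.diag(G).copy()
    usable = var > _RIDGE_TOL * max(float(var.max(initial=0.0)), 1.0)
    if not usable.any() or p == 0:
        warnings.warn("degenerate design: no feature has variance; "
                      "returning an empty model", stacklevel=2)
        return SWLDAModel([], np.empty(0), float(ym), p_enter, p_remove,
                          max_features)

    selected: list[int] = []

    def _beta() -> np.ndarray:
        S = np.asarray(selected)
        return np.linalg.solve(G[np.ix_(S, S)], g[S])

    def _rss() -> float:
        if not selected:
            return syy
        return max(syy - float(g[np.asarray(selected)] @ _beta()), 0.0)

    changed = True
    guard = 0
    while changed and guard < 2 * max(max_features, 1):
        guard += 1
        changed = False

        # --- forward entry -------------------------------------------------
        if len(selected) < max_features:
            cand = np.array([j for j in range(p)
                             if usable[j] and j not in selected])
            if cand.size:
                k = len(selected)
                dof = n - (k + 1) - 1
                if dof >= 1:
                    rss = _rss()
                    if selected:
                        S = np.asarray(selected)
                        Gss = G[np.ix_(S, S)]
                        B = np.linalg.solve(Gss, G[np.ix_(S, cand)])
                        d = var[cand] - np.einsum("ij,ij->j",
                                                  G[np.ix_(S, cand)], B)
                        beta = np.linalg.solve(Gss, g[S])
                        num = g[cand] - G[np.ix_(S, cand)].T @ beta
                    else:
                        d = var[cand]
                        num = g[cand]
                    ok = d > _RIDGE_TOL * np.maximum(var[cand], 1.0)
                    red = np.where(ok, num**2 / np.where(ok, d, 1.0), -np.inf)
                    red = np.minimum(red, rss)  # numerical safety
                    denom = (rss - red) / dof
                    with np.errstate(divide="ignore", invalid="ignore"):
                        F = np.where(denom > 0, red / denom, np.inf)
                    pvals = np.where(np.isfinite(red),
                                     stats.f.sf(F, 1, dof), np.inf)
                    best = int(np.argmin(pvals))  # ties -> lowest index
                    if pvals[best] < p_enter and np.isfinite(red[best]):
                        selected.append(int(cand[best]))
                        changed = True

        # --- backward removal ---------------------------------------------
        while selected:
            S = np.asarray(selected)
            k = len(selected)
            dof = n - k - 1
            if dof < 1:
                break
            Gss = G[np.ix_(S, S)]
            A = np.linalg.inv(Gss)
            beta = A @ g[S]
            rss = max(syy - float(g[S] @ beta), 0.0)
            increase = beta**2 / np.diag(A)
            with np.errstate(divide="ignore", invalid="ignore"):
                F = increase / (rss / dof) if rss > 0 else np.full(k, np.inf)
            pvals = stats.f.sf(F, 1, dof)
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                del selected[worst]
                changed = True
            else:
                break

    if selected:
        beta = _beta()
        S = np.asarray(selected)
        intercept = float(ym - xm[S] @ beta)
    else:
        beta = np.empty(0)
        intercept = float(ym)
    return SWLDAModel(list(selected), beta, intercept, p_enter, p_remove,
                      max_features)


def score(model: SWLDAModel, X: np.ndarray) -> np.ndarray:
    """Linear read-out ``intercept + X[:, selected] · weights`` per item."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be items × features")
    if not model.selected:
        return np.full(X.shape[0], model.intercept)
    if max(model.selected) >= X.shape[1]:
        raise ValueError("X lacks columns the model selected")
    return model.intercept + X[:, model.selected] @ model.weights
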