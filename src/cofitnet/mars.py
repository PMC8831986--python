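"""Additive multivariate adaptive regression splines (degree 1).

The model is a sum of mirrored hinge functions max(0, x_j - t) and
max(0, t - x_j) at knots t placed on observed feature values.  The forward
pass greedily adds the mirrored pair that most reduces residual sum of
squares; the backward pass prunes terms by generalized cross-validation

    GCV(M) = (RSS / N) / (1 - eff(M) / N)^2,
    eff(M) = M + penalty * (M - 1) / 2,

with M the number of basis functions including the intercept.  For edge
classification the model is fitted by least squares to 0/1 labels and its
output clipped to [0, 1] — the standard regression-as-classification
shortcut for this model family; the raw (unclipped) prediction remains
available for regression use.

Knot search is exhaustive over observed values up to ``max_knots`` distinct
candidates per feature; beyond that the candidate set is thinned to evenly
spaced order statistics (still observed values).  Candidate evaluation is
vectorized: all hinges of a feature are projected against the current
orthonormalized design at once, so each forward step costs one matrix
product per feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MarsModel", "fit_mars"]

# basis term encodings
_INTERCEPT = ("intercept",)


def _hinge(x: np.ndarray, knot: float, sign: int) -> np.ndarray:
    return np.maximum(0.0, sign * (x - knot))


def _design(X: np.ndarray, terms: list[tuple]) -> np.ndarray:
    cols = []
    for t in terms:
        if t[0] == "intercept":
            cols.append(np.ones(X.shape[0]))
        else:
            _, j, knot, sign = t
            cols.append(_hinge(X[:, j], knot, sign))
    return np.column_stack(cols)


@dataclass
class MarsModel:
    """A fitted additive hinge model."""

    terms: list[tuple]
    coef: np.ndarray
    gcv_: float
    gcv_path_: list[float] = field(default_factory=list)  # GCV of every candidate model seen in pruning
    training_r2_: float = float("nan")
    penalty: float = 3.0

    @property
    def n_basis(self) -> int:
        return len(self.terms)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Raw model output (no clipping)."""
        X = np.asarray(X, dtype=float)
        return _design(X, self.terms) @ self.coef

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Classification scores: raw output clipped to [0, 1]."""
        return np.clip(self.predict(X), 0.0, 1.0)

    def describe(self) -> list[str]:
        out = []
        for t, c in zip(self.terms, self.coef):
            if t[0] == "intercept":
                out.append(f"{c:+.4g}")
            else:
                _, j, knot, sign = t
                arg = f"x{j}-{knot:.4g}" if sign > 0 else f"{knot:.4g}-x{j}"
                out.append(f"{c:+.4g}*max(0,{arg})")
        return out


def _gcv(rss: float, n: int, m: int, penalty: float) -> float:
    eff = m + penalty * (m - 1) / 2.0
    if eff >= n:
        return float("inf")
    return (rss / n) / (1.0 - eff / n) ** 2


def _candidate_knots(col: np.ndarray, max_knots: int) -> np.ndarray:
    uniq = np.unique(col)
    if len(uniq) <= max_knots:
        return uniq
    idx = np.linspace(0, len(uniq) - 1, max_knots).round().astype(int)
    return uniq[np.unique(idx)]


def fit_mars(
    X: np.ndarray,
    y: np.ndarray,
    max_terms: int = 21,
    penalty: float = 3.0,
    max_knots: int = 128,
    thresh: float = 1e-3,
) -> MarsModel:
    """Fit an additive MARS model by forward growth and GCV pruning.

    ``max_terms`` caps the number of basis functions (intercept included)
    grown by the forward pass; mirrored pairs are added whole, so growth
    stops at or one below the cap.  The forward pass also stops when the
    best candidate pair improves training R^2 by less than ``thresh`` —
    the customary forward stopping rule for this model family.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, p) with matching y")
    n, p = X.shape
    if n < 2 * max_terms:
        raise ValueError(f"need at least 2*max_terms = {2 * max_terms} rows, got {n}")

    y_mean = float(y.mean())
    base_rss = float(np.sum((y - y_mean) ** 2))
    if np.ptp(y) == 0.0:
        warnings.warn("constant response: returning intercept-only model")
        model = MarsModel(
            terms=[_INTERCEPT], coef=np.array([y_mean]), gcv_=_gcv(0.0, n, 1, penalty),
            penalty=penalty,
        )
        model.training_r2_ = 1.0
        return model

    terms: list[tuple] = [_INTERCEPT]
    B = np.ones((n, 1))
    knot_sets = [_candidate_knots(X[:, j], max_knots) for j in range(p)]

    # ---- forward pass ----
    while len(terms) + 2 <= max_terms:
        Q, _ = np.linalg.qr(B)
        r = y - Q @ (Q.T @ y)
        rss_now = float(r @ r)
        best = None  # (reduction, j, knot)
        for j in range(p):
            knots = knot_sets[j]
            col = X[:, j][:, None]
            Hp = np.maximum(0.0, col - knots[None, :])
            Hm = np.maximum(0.0, knots[None, :] - col)
            Hp -= Q @ (Q.T @ Hp)
            Hm -= Q @ (Q.T @ Hm)
            a11 = np.einsum("ij,ij->j", Hp, Hp)
            a22 = np.einsum("ij,ij->j", Hm, Hm)
            a12 = np.einsum("ij,ij->j", Hp, Hm)
            b1 = Hp.T @ r
            b2 = Hm.T @ r
            det = a11 * a22 - a12**2
            eps = 1e-12 * max(rss_now, 1.0)
            red = np.zeros(len(knots))
            ok = det > eps
            with np.errstate(divide="ignore", invalid="ignore"):
                beta1 = np.where(ok, (b1 * a22 - b2 * a12) / det, 0.0)
                beta2 = np.where(ok, (b2 * a11 - b1 * a12) / det, 0.0)
            red = np.where(ok, beta1 * b1 + beta2 * b2, red)
            # rank-1 fallback: only one of the mirrored columns informative
            r1 = np.where(a11 > eps, b1**2 / np.where(a11 > eps, a11, 1.0), 0.0)
            r2 = np.where(a22 > eps, b2**2 / np.where(a22 > eps, a22, 1.0), 0.0)
            red = np.maximum(red, np.maximum(r1, r2))
            k_best = int(np.argmax(red))
            if best is None or red[k_best] > best[0] + 1e-15:
                best = (float(red[k_best]), j, float(knots[k_best]))
        if best is None or best[0] <= thresh * base_rss:
            break
        _, j, knot = best
        terms.append(("hinge", j, knot, 1))
        terms.append(("hinge", j, knot, -1))
        B = _design(X, terms)

    # ---- backward pass (prune by GCV) ----
    def _rss(term_list: list[tuple]) -> float:
        D = _design(X, term_list)
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ coef
        return float(resid @ resid), coef

    current = list(terms)
    rss_cur, coef_cur = _rss(current)
    gcv_path = [_gcv(rss_cur, n, len(current), penalty)]
    best_terms, best_coef = list(current), coef_cur
    best_gcv = gcv_path[0]

    while len(current) > 1:
        trial_best = None  # (gcv, terms, coef)
        for i in range(1, len(current)):  # never drop the intercept
            trial = current[:i] + current[i + 1 :]
            rss_t, coef_t = _rss(trial)
            gcv_t = _gcv(rss_t, n, len(trial), penalty)
            if trial_best is None or gcv_t < trial_best[0]:
                trial_best = (gcv_t, trial, coef_t)
        gcv_t, current, coef_cur = trial_best
        gcv_path.append(gcv_t)
        if gcv_t < best_gcv:
            best_gcv, best_terms, best_coef = gcv_t, list(current), coef_cur

    model = MarsModel(
        terms=best_terms,
        coef=np.asarray(best_coef),
        gcv_=best_gcv,
        gcv_path_=gcv_path,
        penalty=penalty,
    )
    pred = model.predict(X)
    model.training_r2_ = 1.0 - float(np.sum((y - pred) ** 2)) / base_rss
    return model
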