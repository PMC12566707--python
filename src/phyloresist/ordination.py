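"""Redundancy analysis (RDA), VIF screening and variance partitioning.

RDA regresses the (standardized) response block Y on the predictor block X
and eigendecomposes the fitted values: the constrained axes are the principal
axes of the part of Y that X explains.  Explanatory power is reported as the
Ezekiel-adjusted R-squared; significance comes from unrestricted row
permutations of the predictors against the pseudo-F statistic.  Variance
partitioning splits the adjusted R-squared of the full model into fractions
unique to the invader-cover predictor, unique to the soil block, and shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError


def _as_matrix(a, name: str) -> tuple[np.ndarray, list[str], list]:
    if isinstance(a, pd.DataFrame):
        return a.to_numpy(dtype=float), list(map(str, a.columns)), list(a.index)
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"{name}{i}" for i in range(arr.shape[1])], list(range(arr.shape[0]))


def _standardize(m: np.ndarray) -> np.ndarray:
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValidationError("constant column cannot be standardized")
    return (m - mean) / sd


def _r2(y: np.ndarray, x: np.ndarray) -> float:
    """Fraction of total variance of centered y captured by least squares on x."""
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ coef
    total = (yc**2).sum()
    return 0.0 if total == 0 else float((fitted**2).sum() / total)


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel correction: 1 - (1 - R^2) (n - 1)/(n - m - 1)."""
    if n - m - 1 <= 0:
        raise ValidationError("adjusted R^2 undefined: n <= m + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def vif(X) -> dict[str, float]:
    """Variance inflation factor 1/(1 - R_j^2) for each predictor column."""
    x, names, _ = _as_matrix(X, "x")
    if x.shape[1] < 2:
        raise ValidationError("VIF needs at least 2 predictors")
    if x.shape[0] <= x.shape[1]:
        raise ValidationError("VIF needs more rows than predictors")
    out = {}
    for j, name in enumerate(names):
        others = np.delete(x, j, axis=1)
        r2 = _r2(x[:, [j]], others)
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class VpaFractions:
    """Adjusted-R^2 variance partition between cover and the soil block.

    Raw fractions may be slightly negative (a known property of adjusted-R^2
    partitions); ``clamped()`` zeroes them for display.  Fractions are of
    total response variance; ``of_explained()`` renormalizes the three
    explained parts to sum to 1.
    """

    unique_cover: float
    unique_soil: float
    shared: float
    unexplained: float

    def as_dict(self) -> dict:
        return {
            "unique_cover": self.unique_cover,
            "unique_soil": self.unique_soil,
            "shared": self.shared,
            "unexplained": self.unexplained,
        }

    @property
    def has_negative(self) -> bool:
        return min(self.unique_cover, self.unique_soil, self.shared) < 0

    def clamped(self) -> dict:
        c = {k: max(v, 0.0) for k, v in self.as_dict().items()}
        return c

    def of_explained(self) -> dict:
        parts = {
            k: max(v, 0.0)
            for k, v in self.as_dict().items()
            if k != "unexplained"
        }
        total = sum(parts.values())
        if total <= 0:
            return {k: 0.0 for k in parts}
        return {k: v / total for k, v in parts.items()}


class RDA:
    """Redundancy analysis model: constrained ordination of Y on X.

    Both blocks are z-standardized by default (correlation-scale RDA),
    appropriate when responses mix units.  ``fit`` runs the permutation
    tests and returns an :class:`RDAResults`.
    """

    def __init__(self, Y, X, scale: bool = True):
        self.Y_raw, self.response_names, idx_y = _as_matrix(Y, "y")
        self.X_raw, self.predictor_names, idx_x = _as_matrix(X, "x")
        if self.Y_raw.shape[0] != self.X_raw.shape[0]:
            raise ValidationError("Y and X must have the same number of rows")
        n, m = self.X_raw.shape
        if n <= m + 1:
            raise ValidationError(
                f"need more plots ({n}) than predictors + 1 ({m + 1})"
            )
        rank = np.linalg.matrix_rank(self.X_raw - self.X_raw.mean(axis=0))
        if rank < m:
            corr = np.corrcoef(self.X_raw, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise ValidationError(
                "rank-deficient predictor matrix; most collinear pair: "
                f"{self.predictor_names[i]!r} and {self.predictor_names[j]!r}"
            )
        self.scale = scale
        self.Y = _standardize(self.Y_raw) if scale else self.Y_raw - self.Y_raw.mean(axis=0)
        self.X = _standardize(self.X_raw) if scale else self.X_raw - self.X_raw.mean(axis=0)
        self.row_labels = idx_y

    # -- core computation -------------------------------------------------
    def _fitted(self, X: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(X, self.Y, rcond=None)
        return X @ coef

    def _pseudo_f(self, X: np.ndarray) -> float:
        n, m = X.shape
        fitted = self._fitted(X)
        ss_fit = (fitted**2).sum()
        ss_res = ((self.Y - fitted) ** 2).sum()
        if ss_res <= 0:
            return float("inf")
        return (ss_fit / m) / (ss_res / (n - m - 1))

    def fit(self, n_permutations: int = 999, seed: int | None = None) -> "RDAResults":
        import warnings

        n, m = self.X.shape
        if n_permutations < 99:
            warnings.warn(
                f"only {n_permutations} permutations; p-values will be coarse",
                stacklevel=2,
            )
        fitted = self._fitted(self.X)
        u, sing, vt = np.linalg.svd(fitted, full_matrices=False)
        eig = sing**2 / (n - 1)
        keep = eig > max(eig.max(), 1.0) * 1e-12 if eig.size else np.array([], bool)
        eig = eig[keep]
        u, sing, vt = u[:, keep], sing[keep], vt[keep]
        ss_total = (self.Y**2).sum()
        r2 = float((fitted**2).sum() / ss_total)
        r2_adj = adjusted_r2(r2, n, m)

        rng = np.random.default_rng(seed)
        f_obs = self._pseudo_f(self.X)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if self._pseudo_f(self.X[perm]) >= f_obs:
                exceed += 1
        global_p = (1 + exceed) / (1 + n_permutations)

        # marginal (type III) term tests: permute one predictor's values,
        # holding the others fixed, against its marginal SS contribution
        term_p = {}
        r2_full = r2
        for j, name in enumerate(self.predictor_names):
            others = np.delete(self.X, j, axis=1)
            marg_obs = r2_full - _r2(self.Y, others) if m > 1 else r2_full
            exceed = 0
            for _ in range(n_permutations):
                xj = self.X[:, [j]][rng.permutation(n)]
                xp = np.hstack([others, xj]) if m > 1 else xj
                marg = _r2(self.Y, xp) - (_r2(self.Y, others) if m > 1 else 0.0)
                if marg >= marg_obs:
                    exceed += 1
            term_p[name] = (1 + exceed) / (1 + n_permutations)

        vifs = vif(pd.DataFrame(self.X_raw, columns=self.predictor_names)) if m >= 2 else {
            self.predictor_names[0]: 1.0
        }

        site_scores = u * sing
        return RDAResults(
            model=self,
            eigenvalues=eig,
            site_scores=site_scores,
            response_loadings=vt.T,
            r2=r2,
            r2_adjusted=r2_adj,
            global_p=float(global_p),
            term_p=term_p,
            vif=vifs,
            n_permutations=n_permutations,
            seed=seed,
        )


class RDAResults:
    """Constrained-ordination results with permutation p-values."""

    def __init__(
        self, model, eigenvalues, site_scores, response_loadings,
        r2, r2_adjusted, global_p, term_p, vif, n_permutations, seed,
    ):
        self.model = model
        self.eigenvalues = eigenvalues
        self.site_scores = site_scores
        self.response_loadings = response_loadings
        self.r2 = r2
        self.r2_adjusted = r2_adjusted
        self.global_p = global_p
        self.term_p = term_p
        self.vif = vif
        self.n_permutations = n_permutations
        self.seed = seed

    @property
    def explained_fraction_per_axis(self) -> np.ndarray:
        """Percent of constrained variance carried by each RDA axis."""
        tot = self.eigenvalues.sum()
        return 100.0 * self.eigenvalues / tot if tot > 0 else self.eigenvalues

    def biplot_scores(self) -> pd.DataFrame:
        """Predictor arrows: correlations of X columns with the site scores."""
        arrows = np.array(
            [
                [
                    np.corrcoef(self.model.X[:, j], self.site_scores[:, k])[0, 1]
                    if self.site_scores[:, k].std() > 0
                    else 0.0
                    for k in range(self.site_scores.shape[1])
                ]
                for j in range(self.model.X.shape[1])
            ]
        )
        return pd.DataFrame(
            arrows,
            index=self.model.predictor_names,
            columns=[f"RDA{k + 1}" for k in range(arrows.shape[1])],
        )

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "r2_adjusted": self.r2_adjusted,
            "global_p": self.global_p,
            "term_p": dict(self.term_p),
            "vif": dict(self.vif),
            "eigenvalues": list(map(float, self.eigenvalues)),
            "explained_fraction_per_axis": list(
                map(float, self.explained_fraction_per_axis)
            ),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }

    def summary(self) -> str:
        lines = [
            "Redundancy analysis",
            f"  responses:  {', '.join(self.model.response_names)}",
            f"  predictors: {', '.join(self.model.predictor_names)}",
            f"  R^2 = {self.r2:.4f}   adjusted R^2 = {self.r2_adjusted:.4f}   "
            f"global p = {self.global_p:.4f} ({self.n_permutations} permutations)",
            "  axis % of constrained variance: "
            + ", ".join(f"{v:.1f}" for v in self.explained_fraction_per_axis),
            "  term p-values: "
            + ", ".join(f"{k}={v:.4f}" for k, v in self.term_p.items()),
            "  VIF: " + ", ".join(f"{k}={v:.2f}" for k, v in self.vif.items()),
        ]
        return "\n".join(lines)


def variance_partition(Y, cover, soil, scale: bool = True) -> VpaFractions:
    """Partition adjusted R^2 of Y between invader cover and the soil block.

    full = adjR2(Y ~ cover + soil); unique_cover = full - adjR2(Y ~ soil);
    unique_soil = full - adjR2(Y ~ cover); shared = full - unique_cover -
    unique_soil; unexplained = 1 - full.
    """
    y, _, _ = _as_matrix(Y, "y")
    c, _, _ = _as_matrix(cover, "cover")
    s, _, _ = _as_matrix(soil, "soil")
    if not (y.shape[0] == c.shape[0] == s.shape[0]):
        raise ValidationError("Y, cover and soil must share the row count")
    n = y.shape[0]
    if scale:
        y, c, s = _standardize(y), _standardize(c), _standardize(s)
    both = np.hstack([c, s])
    full = adjusted_r2(_r2(y, both), n, both.shape[1])
    soil_only = adjusted_r2(_r2(y, s), n, s.shape[1])
    cover_only = adjusted_r2(_r2(y, c), n, c.shape[1])
    a = full - soil_only
    b = full - cover_only
    return VpaFractions(
        unique_cover=a,
        unique_soil=b,
        shared=full - a - b,
        unexplained=1.0 - full,
    )
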