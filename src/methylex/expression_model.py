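"""Polynomial regression of log gene expression on methylation and gene
architecture.

The model space is every monomial of total degree <= 3 over twelve
Z-standardized predictors: the nine region x context methylation measures
plus exon length, intron length and exon count.  Candidate terms are ranked
by a greedy forward search that minimizes the Bayesian information
criterion, and model quality is assessed by k-fold cross-validated
out-of-sample R².

A monomial term is represented by its exponent vector: a tuple of twelve
non-negative integers summing to at most three, aligned with
:data:`PREDICTORS`.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError

logger = logging.getLogger("methylex")

#: canonical predictor order for exponent vectors
PREDICTORS = ["m_cg", "m_chg", "m_chh",
              "u_cg", "u_chg", "u_chh",
              "d_cg", "d_chg", "d_chh",
              "l_exon", "l_intron", "n_exon"]

Exponents = tuple[int, ...]


def term_name(exponents: Exponents,
              predictors: Sequence[str] = PREDICTORS) -> str:
    """Human-readable monomial name, e.g. ``m_cg^2*l_exon``."""
    parts = []
    for name, e in zip(predictors, exponents):
        if e == 1:
            parts.append(name)
        elif e > 1:
            parts.append(f"{name}^{e}")
    return "*".join(parts) if parts else "1"


def term_degree(exponents: Exponents) -> int:
    return sum(exponents)


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Z-standardized predictors and log-expression response.

    ``X`` holds the twelve standardized predictors (mean 0, sample SD 1
    over the fitted rows); ``y`` is log expression in ``log_base``.  The
    per-predictor raw means and SDs are retained so standardized values can
    be mapped back to the raw scale.
    """

    X: pd.DataFrame
    y: pd.Series
    means: pd.Series
    sds: pd.Series
    log_base: float
    n_dropped_missing: int = 0
    n_dropped_zero: int = 0

    @property
    def n(self) -> int:
        return len(self.y)

    def destandardize(self, Z: pd.DataFrame) -> pd.DataFrame:
        """Map standardized predictor values back to the raw scale."""
        return Z * self.sds + self.means


def build_feature_table(region_table: pd.DataFrame,
                        log_base: float = 10.0) -> FeatureTable:
    """Standardize the twelve predictors and log-transform expression.

    Rows with any missing predictor or missing/zero expression are dropped
    (counts logged); standardization uses the sample SD (n-1 denominator)
    computed over the retained rows.
    """
    missing_cols = [c for c in PREDICTORS + ["expression"]
                    if c not in region_table.columns]
    if missing_cols:
        raise ValidationError(f"region table lacks columns: {missing_cols}")
    df = region_table[PREDICTORS + ["expression"]]
    complete = df.notna().all(axis=1)
    n_missing = int((~complete).sum())
    df = df[complete]
    zero = df["expression"] <= 0
    n_zero = int(zero.sum())
    df = df[~zero]
    if len(df) < 3:
        raise ValidationError(
            f"fewer than 3 complete rows ({len(df)}) after filtering")
    if n_missing:
        logger.info("build_feature_table: dropped %d genes with missing "
                    "predictors", n_missing)
    if n_zero:
        logger.info("build_feature_table: dropped %d genes with zero "
                    "expression", n_zero)
    X = df[PREDICTORS].astype(float)
    means = X.mean()
    sds = X.std(ddof=1)
    if (sds == 0).any():
        degenerate = list(sds.index[sds == 0])
        raise ValidationError(f"zero-variance predictors: {degenerate}")
    Z = (X - means) / sds
    y = np.log(df["expression"]) / np.log(log_base)
    return FeatureTable(X=Z, y=y, means=means, sds=sds, log_base=log_base,
                        n_dropped_missing=n_missing, n_dropped_zero=n_zero)


# ---------------------------------------------------------------------------
# term enumeration and design matrices
# ---------------------------------------------------------------------------

def enumerate_terms(n_predictors: int = 12, max_degree: int = 3
                    ) -> list[Exponents]:
    """All distinct non-constant monomials of total degree <= *max_degree*.

    Returned sorted by (total degree, exponent vector); the count is
    C(n + d, d) - 1.
    """
    if n_predictors < 1 or max_degree < 1:
        raise ValueError("n_predictors and max_degree must be >= 1")
    terms: list[Exponents] = []
    for degree in range(1, max_degree + 1):
        for combo in itertools.combinations_with_replacement(
                range(n_predictors), degree):
            exps = [0] * n_predictors
            for idx in combo:
                exps[idx] += 1
            terms.append(tuple(exps))
    terms = sorted(set(terms), key=lambda e: (term_degree(e), e))
    return terms


def design_matrix(X: pd.DataFrame | np.ndarray, terms: Sequence[Exponents],
                  intercept: bool = True) -> np.ndarray:
    """Evaluate monomial columns (plus a leading intercept column)."""
    A = np.asarray(X, dtype=float)
    cols = [np.ones(A.shape[0])] if intercept else []
    for exps in terms:
        col = np.ones(A.shape[0])
        for j, e in enumerate(exps):
            if e:
                col = col * A[:, j] ** e
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((A.shape[0], 0))


# ---------------------------------------------------------------------------
# OLS fit with full ANOVA decomposition
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Least-squares fit summary with the standard ANOVA decomposition."""

    terms: list[Exponents]
    coefficients: np.ndarray        # [intercept, term coefficients...]
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    n: int
    ss_model: float
    ss_error: float
    ss_total: float
    df_model: int
    df_error: int
    bic: float
    mean_response: float

    @property
    def ms_model(self) -> float:
        return self.ss_model / self.df_model if self.df_model else float("nan")

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error

    @property
    def f_ratio(self) -> float:
        return self.ms_model / self.ms_error if self.df_model else float("nan")

    @property
    def f_pvalue(self) -> float:
        if not self.df_model:
            return float("nan")
        return float(stats.f.sf(self.f_ratio, self.df_model, self.df_error))

    @property
    def r_squared(self) -> float:
        return self.ss_model / self.ss_total if self.ss_total > 0 else float("nan")

    @property
    def r_squared_adj(self) -> float:
        if self.ss_total <= 0 or self.df_error <= 0:
            return float("nan")
        return 1 - (self.ss_error / self.df_error) / (self.ss_total / (self.n - 1))

    @property
    def rmse(self) -> float:
        return math.sqrt(self.ss_error / self.df_error)

    def to_spec(self, drop_intercept: bool = False) -> "PolynomialModelSpec":
        terms = [ModelTerm(exponents=e, coefficient=float(c), standard_error=float(se),
                           t_value=float(t), p_value=float(p))
                 for e, c, se, t, p in zip(self.terms, self.coefficients[1:],
                                           self.standard_errors[1:],
                                           self.t_values[1:], self.p_values[1:])]
        intercept = None if drop_intercept else float(self.coefficients[0])
        return PolynomialModelSpec(intercept=intercept, terms=terms)


def gaussian_bic(n: int, ss_error: float, n_terms: int) -> float:
    """BIC of a Gaussian linear model: -2 log L at the MLE plus penalty.

    Parameter count is ``n_terms + 2`` (coefficients, intercept, residual
    variance).  The error sum of squares is floored at a tiny positive
    value so perfect fits remain comparable.
    """
    sse = max(ss_error, 1e-300)
    loglik = -0.5 * n * (math.log(2 * math.pi * sse / n) + 1)
    return -2 * loglik + (n_terms + 2) * math.log(n)


def fit_ols(table: FeatureTable, terms: Sequence[Exponents]) -> ModelFit:
    """Ordinary least squares with intercept over the given monomial terms.

    Raises on rank-deficient designs, naming the collinear terms, and when
    the row count does not exceed the parameter count.
    """
    terms = list(terms)
    if len(set(terms)) != len(terms):
        dup = [term_name(t) for t in terms if terms.count(t) > 1]
        raise ValidationError(f"duplicated terms in term list: {sorted(set(dup))}")
    n = table.n
    k = len(terms)
    if n <= k + 1:
        raise ValidationError(f"{n} rows cannot identify {k + 1} parameters")
    A = design_matrix(table.X, terms)
    # pivoted QR exposes which columns are linearly dependent
    _, R, piv = _qr_pivoted(A)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < A.shape[1]:
        bad = sorted(piv[rank:])
        names = ["intercept" if j == 0 else term_name(terms[j - 1]) for j in bad]
        raise ValidationError(f"rank-deficient design; collinear terms: {names}")

    y = table.y.to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_error = float(resid @ resid)
    ybar = float(y.mean())
    ss_total = float(((y - ybar) ** 2).sum())
    ss_model = ss_total - ss_error

    df_error = n - k - 1
    sigma2 = ss_error / df_error
    XtX_inv = np.linalg.inv(A.T @ A)
    se = np.sqrt(np.clip(sigma2 * np.diag(XtX_inv), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2 * stats.t.sf(np.abs(t), df_error)

    return ModelFit(terms=terms, coefficients=beta, standard_errors=se,
                    t_values=t, p_values=p, n=n, ss_model=ss_model,
                    ss_error=ss_error, ss_total=ss_total, df_model=k,
                    df_error=df_error, bic=gaussian_bic(n, ss_error, k),
                    mean_response=ybar)


def _qr_pivoted(A: np.ndarray):
    from scipy.linalg import qr
    return qr(A, mode="economic", pivoting=True)


# ---------------------------------------------------------------------------
# model specification (serializable)
# ---------------------------------------------------------------------------

@dataclass
class ModelTerm:
    exponents: Exponents
    coefficient: float
    standard_error: float | None = None
    t_value: float | None = None
    p_value: float | None = None

    @property
    def name(self) -> str:
        return term_name(self.exponents)

    @property
    def degree(self) -> int:
        return term_degree(self.exponents)


@dataclass
class PolynomialModelSpec:
    """An intercept plus monomial terms over the twelve standardized predictors."""

    intercept: float | None
    terms: list[ModelTerm] = field(default_factory=list)
    predictors: list[str] = field(default_factory=lambda: list(PREDICTORS))

    def __post_init__(self) -> None:
        seen = set()
        for t in self.terms:
            if t.exponents in seen:
                raise ValidationError(f"duplicate term {term_name(t.exponents)}")
            if term_degree(t.exponents) == 0:
                raise ValidationError("constant term must be the intercept")
            if term_degree(t.exponents) > 3:
                raise ValidationError(
                    f"term {term_name(t.exponents)} exceeds degree 3")
            seen.add(t.exponents)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def predict(self, features: Mapping[str, float] | pd.DataFrame) -> np.ndarray | float:
        return predict(self, features)

    def to_json(self, path=None) -> str:
        payload = {
            "intercept": self.intercept,
            "predictors": self.predictors,
            "terms": [{"exponents": list(t.exponents), "coef": t.coefficient,
                       "se": t.standard_error, "t": t.t_value, "p": t.p_value,
                       "name": t.name}
                      for t in self.terms],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "PolynomialModelSpec":
        try:
            payload = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                payload = json.load(fh)
        terms = [ModelTerm(exponents=tuple(t["exponents"]), coefficient=t["coef"],
                           standard_error=t.get("se"), t_value=t.get("t"),
                           p_value=t.get("p"))
                 for t in payload["terms"]]
        return cls(intercept=payload["intercept"], terms=terms,
                   predictors=payload.get("predictors", list(PREDICTORS)))


def predict(spec: PolynomialModelSpec,
            features: Mapping[str, float] | pd.DataFrame) -> float | np.ndarray:
    """Evaluate a polynomial model at standardized feature values.

    *features* may be a mapping or DataFrame keyed by predictor name; every
    predictor appearing with a non-zero exponent in the model must be
    present.  Returns a scalar for a mapping input, an array for a frame.
    """
    needed = {spec.predictors[j]
              for t in spec.terms for j, e in enumerate(t.exponents) if e}
    if isinstance(features, pd.DataFrame):
        missing = needed - set(features.columns)
        if missing:
            raise ValidationError(f"missing predictors: {sorted(missing)}")
        out = np.full(len(features), spec.intercept or 0.0, dtype=float)
        for t in spec.terms:
            col = np.ones(len(features))
            for j, e in enumerate(t.exponents):
                if e:
                    col = col * features[spec.predictors[j]].to_numpy() ** e
            out += t.coefficient * col
        return out
    missing = needed - set(features)
    if missing:
        raise ValidationError(f"missing predictors: {sorted(missing)}")
    total = spec.intercept or 0.0
    for t in spec.terms:
        value = t.coefficient
        for j, e in enumerate(t.exponents):
            if e:
                value *= features[spec.predictors[j]] ** e
        total += value
    return total


# ---------------------------------------------------------------------------
# stepwise BIC selection
# ---------------------------------------------------------------------------

def stepwise_bic(table: FeatureTable, candidate_terms: Iterable[Exponents],
                 direction: str = "forward",
                 ) -> tuple[PolynomialModelSpec, ModelFit]:
    """Greedy BIC-minimizing term selection.

    Forward mode adds, at each step, the candidate whose inclusion most
    reduces the BIC, stopping when no addition reduces it.  The
    ``"bidirectional"`` mode additionally attempts single-term deletions
    after each addition.  Selection is deterministic: BIC ties (within
    1e-9) are broken by lower total degree, then lexicographically smaller
    exponent vector.

    Internally candidates are orthogonalized incrementally against the
    growing design, so each sweep costs one dot product per candidate.
    """
    if direction not in ("forward", "bidirectional"):
        raise ValueError(f"unknown direction {direction!r}")
    candidates = sorted(set(candidate_terms), key=lambda e: (term_degree(e), e))
    n = table.n
    y = table.y.to_numpy(dtype=float)

    if not candidates:
        logger.warning("stepwise_bic: empty candidate list; returning "
                       "intercept-only model")
        fit = _intercept_only_fit(table)
        return fit.to_spec(), fit

    C = design_matrix(table.X, candidates, intercept=False)
    norms0 = (C ** 2).sum(axis=0)

    # state: orthonormal basis columns of the current design (incl. intercept)
    q0 = np.ones(n) / math.sqrt(n)
    r = y - q0 * (q0 @ y)
    C = C - np.outer(q0, q0 @ C)
    active = norms0 > 0
    selected: list[int] = []
    sse = float(r @ r)
    bic = gaussian_bic(n, sse, 0)

    while True:
        col_norm2 = (C ** 2).sum(axis=0)
        usable = active & (col_norm2 > 1e-10 * np.maximum(norms0, 1e-300))
        if not usable.any():
            break
        proj = C.T @ r
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(usable, proj ** 2 / col_norm2, 0.0)
        sse_new = np.maximum(sse - delta, 0.0)
        k_new = len(selected) + 1
        bic_new = np.where(
            usable,
            _bic_vector(n, sse_new, k_new),
            np.inf)
        best_bic = bic_new.min()
        if not best_bic < bic - 1e-12:
            break
        ties = np.flatnonzero(bic_new <= best_bic + 1e-9)
        j = min(ties, key=lambda idx: (term_degree(candidates[idx]),
                                       candidates[idx]))
        # update the orthogonal state with the chosen column
        q = C[:, j] / math.sqrt(col_norm2[j])
        r = r - q * (q @ r)
        C = C - np.outer(q, q @ C)
        active[j] = False
        selected.append(j)
        sse = float(r @ r)
        bic = gaussian_bic(n, sse, len(selected))

        if direction == "bidirectional" and len(selected) > 1:
            selected, sse, bic, r, C, active = _try_deletions(
                table, candidates, selected, bic, y, norms0)

    terms = sorted((candidates[j] for j in selected),
                   key=lambda e: (term_degree(e), e))
    if not terms:
        fit = _intercept_only_fit(table)
        return fit.to_spec(), fit
    fit = fit_ols(table, terms)
    logger.info("stepwise_bic: selected %d terms, BIC %.2f, R^2 %.4f",
                len(terms), fit.bic, fit.r_squared)
    return fit.to_spec(), fit


def _bic_vector(n: int, sse: np.ndarray, n_terms: int) -> np.ndarray:
    sse = np.maximum(sse, 1e-300)
    return n * (np.log(2 * math.pi * sse / n) + 1) + (n_terms + 2) * math.log(n)


def _try_deletions(table, candidates, selected, bic, y, norms0):
    """One backward pass: drop any term whose removal lowers BIC, then
    rebuild the orthogonal state."""
    n = table.n
    improved = True
    while improved and len(selected) > 1:
        improved = False
        for j in list(selected):
            rest = [k for k in selected if k != j]
            A = design_matrix(table.X, [candidates[k] for k in rest])
            beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
            sse_j = float(((y - A @ beta) ** 2).sum())
            bic_j = gaussian_bic(n, sse_j, len(rest))
            if bic_j < bic - 1e-12:
                selected = rest
                bic = bic_j
                improved = True
                break
    # rebuild orthogonal state from scratch for the surviving set
    C = design_matrix(table.X, candidates, intercept=False)
    q0 = np.ones(n) / math.sqrt(n)
    r = y - q0 * (q0 @ y)
    C = C - np.outer(q0, q0 @ C)
    active = norms0 > 0
    for j in selected:
        col_norm2 = float(C[:, j] @ C[:, j])
        q = C[:, j] / math.sqrt(col_norm2)
        r = r - q * (q @ r)
        C = C - np.outer(q, q @ C)
        active[j] = False
    sse = float(r @ r)
    return selected, sse, gaussian_bic(n, sse, len(selected)), r, C, active


def _intercept_only_fit(table: FeatureTable) -> ModelFit:
    y = table.y.to_numpy(dtype=float)
    n = len(y)
    ybar = float(y.mean())
    sse = float(((y - ybar) ** 2).sum())
    se = math.sqrt(sse / (n - 1) / n)
    t = ybar / se if se > 0 else float("inf")
    return ModelFit(terms=[], coefficients=np.array([ybar]),
                    standard_errors=np.array([se]), t_values=np.array([t]),
                    p_values=np.array([2 * stats.t.sf(abs(t), n - 1)]),
                    n=n, ss_model=0.0, ss_error=sse, ss_total=sse,
                    df_model=0, df_error=n - 1,
                    bic=gaussian_bic(n, sse, 0), mean_response=ybar)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValidation:
    """Out-of-sample R² per fold for a fixed term set."""

    k: int
    seed: int | None
    fold_r2: list[float]
    fold_sizes: list[int]
    assignments: np.ndarray     # fold index per row, in table order

    @property
    def min_r2(self) -> float:
        return min(self.fold_r2)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))


def kfold_cv(table: FeatureTable, terms: Sequence[Exponents], k: int = 3,
             seed: int | None = None) -> CrossValidation:
    """K-fold cross-validated out-of-sample R².

    Rows are partitioned at random into *k* folds whose sizes differ by at
    most one; each fold is predicted by the model fitted on the remaining
    folds and scored as ``1 - SSE_heldout / SST_heldout`` (held-out total
    SS centered on the held-out mean).  Fixed *seed* gives identical folds
    and identical scores.
    """
    n = table.n
    terms = list(terms)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k * (len(terms) + 2):
        raise ValidationError(
            f"{n} rows are insufficient for {k}-fold CV of {len(terms)} terms")
    rng = np.random.default_rng(seed)
    assignment = np.repeat(np.arange(k), (n + k - 1) // k)[:n]
    rng.shuffle(assignment)

    A = design_matrix(table.X, terms)
    y = table.y.to_numpy(dtype=float)
    r2, sizes = [], []
    for fold in range(k):
        test = assignment == fold
        beta, _, _, _ = np.linalg.lstsq(A[~test], y[~test], rcond=None)
        resid = y[test] - A[test] @ beta
        sst = float(((y[test] - y[test].mean()) ** 2).sum())
        r2.append(1.0 - float(resid @ resid) / sst)
        sizes.append(int(test.sum()))
    return CrossValidation(k=k, seed=seed, fold_r2=r2, fold_sizes=sizes,
                           assignments=assignment)
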