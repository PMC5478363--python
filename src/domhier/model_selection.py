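"""AICc model selection over developmental-treatment predictors.

The question the selection answers: which of Sex, food Amount and
begging Effort (and their interactions) predict a bird's overall
David's score or overall perch position?  Candidate ordinary
least-squares models are compared by the small-sample Akaike criterion

    ``AICc = -2 loglik + 2p + 2p(p+1) / (n - p - 1)``

with ``p`` counting every estimated parameter including the residual
variance.  The best (lowest-AICc) model plus any model within 2 units
of it form the retained set; Akaike weights
``exp(-delta_i/2) / sum_j exp(-delta_j/2)`` quantify relative support.

The main candidate set holds 15 models over the three factors:
intercept-only; each single main effect; each pair of mains with and
without its two-way interaction; all three mains; all three mains plus
one two-way; and the full model with every interaction up to the
three-way.  Models with two two-way interactions but no three-way are
deliberately not enumerated.  Follow-up comparisons ask whether skeletal
size (tarsus) and body weight mediate any retained effect, and whether
standardized developmental telomere change (delta_tl) adds or replaces
predictive power on the subset of birds where it was measured.

Factors are treatment-coded with references F / Lean / Easy, so
reported coefficients are offsets for being male, Plenty-reared and
Hard-reared respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "FittedModel",
    "ModelTable",
    "FACTOR_CODING",
    "COVARIATES",
    "enumerate_main_candidates",
    "fit_ols",
    "aicc",
    "rank_models",
    "fit_candidates",
    "mediator_comparison",
    "dtl_comparison",
]

# factor -> (non-reference level, coefficient label); references F / Lean / Easy
FACTOR_CODING: dict[str, tuple[str, str]] = {
    "sex": ("M", "sexM"),
    "amount": ("Plenty", "amountPlenty"),
    "effort": ("Hard", "effortHard"),
}
COVARIATES = ("tarsus", "weight", "delta_tl")
MAIN_FACTORS = ("sex", "amount", "effort")


def _canon_term(term: Sequence[str] | str) -> tuple[str, ...]:
    if isinstance(term, str):
        term = term.split(":")
    term = tuple(sorted(term))
    for v in term:
        if v not in FACTOR_CODING and v not in COVARIATES:
            raise ValueError(f"unknown model term variable {v!r}")
    if len(term) > 1 and any(v in COVARIATES for v in term):
        raise ValueError(f"interactions with covariates are not part of the candidate space: {term}")
    return term


@dataclass(frozen=True)
class ModelSpec:
    """A candidate linear model: a response and a set of terms.

    Terms are tuples of variable names; length-1 tuples are main effects
    or covariates, longer tuples are interactions.  Marginality is
    enforced: an interaction may only appear alongside all its
    lower-order constituent terms.
    """

    response: str
    terms: frozenset[tuple[str, ...]] = frozenset()

    def __post_init__(self) -> None:
        canon = frozenset(_canon_term(t) for t in self.terms)
        object.__setattr__(self, "terms", canon)
        for t in canon:
            if len(t) > 1:
                for r in range(1, len(t)):
                    for sub in combinations(t, r):
                        if tuple(sorted(sub)) not in canon:
                            raise ValueError(
                                f"term {':'.join(t)} requires its lower-order term {':'.join(sub)}"
                            )

    @property
    def label(self) -> str:
        if not self.terms:
            return "1"
        ordered = sorted(self.terms, key=lambda t: (len(t), t))
        return " + ".join(":".join(t) for t in ordered)

    def with_terms(self, *extra: Sequence[str] | str) -> "ModelSpec":
        return ModelSpec(self.response, self.terms | {_canon_term(t) for t in extra})


@dataclass
class FittedModel:
    """An OLS fit of one :class:`ModelSpec` with its AICc."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # index: term label; columns: estimate, ci_low, ci_high
    loglik: float
    n: int
    p: int  # estimated parameters, residual variance included
    aicc: float
    row_index: frozenset = field(default_factory=frozenset, repr=False)


@dataclass
class ModelTable:
    """Ranked candidate models with AICc deltas, weights and retention.

    ``table`` is sorted by AICc; ``retained`` flags models within
    ``threshold`` (default 2) AICc units of the best.
    """

    fits: list[FittedModel]
    threshold: float = 2.0
    table: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        aiccs = np.array([f.aicc for f in self.fits])
        order = np.argsort(aiccs, kind="stable")
        self.fits = [self.fits[i] for i in order]
        aiccs = aiccs[order]
        delta = aiccs - aiccs[0]
        rel = np.exp(-delta / 2.0)
        weight = rel / rel.sum()
        self.table = pd.DataFrame(
            {
                "model": [f.spec.label for f in self.fits],
                "loglik": [f.loglik for f in self.fits],
                "p": [f.p for f in self.fits],
                "aicc": aiccs,
                "delta": delta,
                "weight": weight,
                "retained": delta <= self.threshold,
            }
        )

    @property
    def best(self) -> FittedModel:
        return self.fits[0]

    @property
    def retained_specs(self) -> list[ModelSpec]:
        return [f.spec for f, keep in zip(self.fits, self.table["retained"]) if keep]


def enumerate_main_candidates(response: str = "davids_overall") -> list[ModelSpec]:
    """The 15-model main candidate set over Sex, Amount and Effort.

    1 intercept-only + 3 single mains + 3 pairs of mains + 3 pairs with
    their two-way interaction + 1 all-three-mains + 3 all mains with one
    two-way + 1 full model (all two-ways and the three-way) = 15.
    """
    a, b, c = MAIN_FACTORS
    specs = [ModelSpec(response)]
    for f in MAIN_FACTORS:
        specs.append(ModelSpec(response, frozenset({(f,)})))
    for f, g in combinations(MAIN_FACTORS, 2):
        specs.append(ModelSpec(response, frozenset({(f,), (g,)})))
    for f, g in combinations(MAIN_FACTORS, 2):
        specs.append(ModelSpec(response, frozenset({(f,), (g,), tuple(sorted((f, g)))})))
    mains = frozenset({(a,), (b,), (c,)})
    specs.append(ModelSpec(response, mains))
    for f, g in combinations(MAIN_FACTORS, 2):
        specs.append(ModelSpec(response, mains | {tuple(sorted((f, g)))}))
    full = mains | {tuple(sorted(t)) for t in combinations(MAIN_FACTORS, 2)} | {tuple(sorted(MAIN_FACTORS))}
    specs.append(ModelSpec(response, full))
    assert len(specs) == 15 and len({s.terms for s in specs}) == 15
    return specs


def _term_column(term: tuple[str, ...], data: pd.DataFrame) -> tuple[str, np.ndarray]:
    cols = []
    labels = []
    for v in term:
        if v in FACTOR_CODING:
            level, label = FACTOR_CODING[v]
            cols.append((data[v] == level).to_numpy(dtype=float))
            labels.append(label)
        else:
            cols.append(data[v].to_numpy(dtype=float))
            labels.append(v)
    return ":".join(labels), np.prod(cols, axis=0)


def design_matrix(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Treatment-coded design matrix (with intercept) for a spec."""
    out = {"Intercept": np.ones(len(data))}
    for term in sorted(spec.terms, key=lambda t: (len(t), t)):
        label, col = _term_column(term, data)
        out[label] = col
    return pd.DataFrame(out, index=data.index)


def fit_ols(spec: ModelSpec, data: pd.DataFrame) -> FittedModel:
    """Fit one candidate model by OLS and attach its AICc.

    ``data`` must contain the response column named by ``spec.response``
    and every predictor the spec uses, with no missing values in those
    columns.  The log-likelihood is the Gaussian maximum-likelihood
    value; ``p`` counts intercept + slopes + residual variance.
    Coefficient CIs come from the t distribution.  A rank-deficient
    design raises a ValueError naming the collinear columns.
    """
    needed = [spec.response] + sorted({v for t in spec.terms for v in t})
    if data[needed].isna().any().any():
        bad = [c for c in needed if data[c].isna().any()]
        raise ValueError(f"missing values in column(s) {bad}; subset rows first")
    y = data[spec.response].to_numpy(dtype=float)
    X = design_matrix(spec, data)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for model {spec.label!r}: columns {list(X.columns)}"
            f" span rank {rank} < {X.shape[1]} (collinear or constant term)"
        )
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    coeffs = pd.DataFrame(
        {"estimate": res.params, "ci_low": ci[0], "ci_high": ci[1]}
    )
    n = len(y)
    p = X.shape[1] + 1  # + residual variance
    return FittedModel(
        spec=spec,
        coefficients=coeffs,
        loglik=float(res.llf),
        n=n,
        p=p,
        aicc=aicc(float(res.llf), p, n),
        row_index=frozenset(data.index),
    )


def aicc(loglik: float, p: int, n: int) -> float:
    """Small-sample Akaike criterion; undefined when n <= p + 1."""
    if n <= p + 1:
        raise ValueError(f"AICc correction undefined for n={n}, p={p} (need n > p + 1)")
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


def rank_models(fits: Sequence[FittedModel], threshold: float = 2.0) -> ModelTable:
    """Rank fitted models by AICc; models within ``threshold`` are retained.

    All fits must be on the identical set of rows — AICc values computed
    on different data are not comparable.
    """
    if not fits:
        raise ValueError("need at least one fitted model")
    rows = {f.row_index for f in fits}
    if len(rows) > 1:
        raise ValueError("fits use differing row sets; AICc not comparable")
    return ModelTable(fits=list(fits), threshold=threshold)


def fit_candidates(specs: Iterable[ModelSpec], data: pd.DataFrame) -> list[FittedModel]:
    """Fit a candidate set, rejecting (with a warning) rank-deficient specs.

    A spec whose design matrix is singular on this data — a constant
    covariate, or an interaction cell with no birds in it — cannot be
    estimated and is dropped from the comparison rather than aborting
    it.  Duplicate specs (same term set) are fitted once.
    """
    import warnings as _warnings

    seen: dict[frozenset, ModelSpec] = {}
    for s in specs:
        seen.setdefault(s.terms, s)
    fits: list[FittedModel] = []
    for s in seen.values():
        try:
            fits.append(fit_ols(s, data))
        except ValueError as err:
            if "rank-deficient" in str(err):
                _warnings.warn(f"candidate {s.label!r} rejected: {err}", stacklevel=2)
            else:
                raise
    if not fits:
        raise ValueError("every candidate model was rank-deficient on this data")
    return fits


def _fit_all(specs: Iterable[ModelSpec], data: pd.DataFrame, threshold: float) -> ModelTable:
    return rank_models(fit_candidates(specs, data), threshold=threshold)


def mediator_comparison(
    best_specs: Sequence[ModelSpec],
    data: pd.DataFrame,
    threshold: float = 2.0,
) -> ModelTable:
    """Do tarsus length and/or body weight mediate the retained effects?

    Candidate set: each best main-analysis model; each best model plus
    tarsus, plus weight, plus both; and the mediators replacing the
    original terms entirely (tarsus-only, weight-only, both).  All fits
    use rows with tarsus and weight present.
    """
    if not best_specs:
        raise ValueError("need at least one best model spec")
    response = best_specs[0].response
    sub = data.dropna(subset=["tarsus", "weight"])
    specs: list[ModelSpec] = []
    for s in best_specs:
        specs += [s, s.with_terms("tarsus"), s.with_terms("weight"), s.with_terms("tarsus", "weight")]
    specs += [
        ModelSpec(response, frozenset({("tarsus",)})),
        ModelSpec(response, frozenset({("weight",)})),
        ModelSpec(response, frozenset({("tarsus",), ("weight",)})),
    ]
    return _fit_all(specs, sub, threshold)


def dtl_comparison(
    best_specs: Sequence[ModelSpec],
    data: pd.DataFrame,
    threshold: float = 2.0,
) -> ModelTable:
    """Does developmental telomere change add or replace predictive power?

    The best main-analysis model(s) are refit on the subset of birds
    with delta_tl measured and compared to the same models with delta_tl
    added, and to delta_tl alone.
    """
    if not best_specs:
        raise ValueError("need at least one best model spec")
    response = best_specs[0].response
    sub = data.dropna(subset=["delta_tl"])
    specs: list[ModelSpec] = []
    for s in best_specs:
        specs += [s, s.with_terms("delta_tl")]
    specs.append(ModelSpec(response, frozenset({("delta_tl",)})))
    return _fit_all(specs, sub, threshold)
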