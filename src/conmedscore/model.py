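"""Covariate-table assembly, collinearity pruning, and backward BIC
selection for the drug-response linear model.

The response (phenotype change over the treatment window) is modelled
as ``y = β0 + β1 x1 + ... + βn xn + ε`` by ordinary least squares.
Certain covariates — treatment-arm indicators, the leading genotype
principal components, and the pre-treatment phenotype — are forced into
every model; concomitant-medication scores enter as dummy-variable
groups against referent score 0 and are added or removed en bloc.
Selection is greedy backward elimination on the Bayesian information
criterion: at each step the removable unit whose deletion lowers BIC
the most is dropped, until no deletion lowers it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CovariateSpec:
    """One selectable unit: a column or an en-bloc dummy group."""

    name: str
    kind: str  # "continuous" | "indicator" | "dummy_group"
    forced: bool = False
    group_members: tuple[str, ...] = ()

    @property
    def columns(self) -> tuple[str, ...]:
        return self.group_members if self.kind == "dummy_group" else (self.name,)


@dataclass
class FitResult:
    n: int
    coefficients: pd.DataFrame  # columns: name, beta, se, p
    rss: float
    k: int  # parameters incl. intercept
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        self.bic = compute_bic(self.n, self.rss, self.k)

    def beta(self, name: str) -> float:
        return float(self.coefficients.set_index("name").loc[name, "beta"])


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; offending columns are listed."""


def fit_linear(y, X: pd.DataFrame) -> FitResult:
    """OLS with intercept; betas, SEs and t-based two-sided p-values.

    Raises :class:`RankDeficientError` (naming linearly dependent
    columns) rather than silently pseudo-inverting, and errors when the
    fit is exact (BIC undefined at rss = 0).
    """
    y = np.asarray(y, dtype=float)
    names = ["Intercept"] + list(X.columns)
    A = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    n, k = A.shape
    if n <= k:
        raise ValueError(f"need n > k parameters (n={n}, k={k})")
    rank = np.linalg.matrix_rank(A)
    if rank < k:
        # identify columns linearly dependent on their predecessors
        dep = []
        for j in range(1, k):
            if np.linalg.matrix_rank(A[:, : j + 1]) == np.linalg.matrix_rank(A[:, :j]):
                dep.append(names[j])
        raise RankDeficientError(f"rank-deficient design; dependent column(s): {dep}")
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        raise ValueError("perfect fit (rss = 0): BIC undefined")
    sigma2 = rss / (n - k)
    xtx_inv = np.linalg.inv(A.T @ A)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=n - k)
    coef = pd.DataFrame({"name": names, "beta": beta, "se": se, "p": p})
    return FitResult(n=n, coefficients=coef, rss=rss, k=k)


def compute_bic(n: int, rss: float, k: int) -> float:
    """Gaussian-profile BIC: ``n·ln(rss/n) + (k+1)·ln(n)``.

    The error variance counts as a parameter; only BIC differences
    within one run are ever compared, so the additive-constant
    convention is fixed but arbitrary.
    """
    if rss <= 0:
        raise ValueError("rss must be positive")
    return float(n * np.log(rss / n) + (k + 1) * np.log(n))


def build_covariate_table(
    responses: pd.Series,
    covariates: pd.DataFrame,
    forced: list[str],
    dummy_groups: dict[str, list[str]] | None = None,
    standardize: bool = True,
    consent: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame, list[CovariateSpec]]:
    """Align response and covariates into a complete-case model table.

    Rows are restricted to subjects present in both inputs (and, when a
    consent flag is given, consenting subjects); any row with a missing
    covariate or response is dropped with a logged count.  Continuous
    columns (more than two distinct values) are optionally standardized
    to mean 0, sd 1.  Dummy-group member columns become one en-bloc
    :class:`CovariateSpec`; a group is forced iff named in ``forced``.
    """
    dummy_groups = dummy_groups or {}
    ids = responses.index.intersection(covariates.index)
    if consent is not None:
        ids = ids.intersection(consent.index[consent.astype(bool)])
    if len(ids) == 0:
        raise ValueError("no overlapping subjects between response and covariates")
    tab = covariates.loc[ids].copy()
    empty = [c for c in tab.columns if tab[c].isna().all()]
    if empty:
        raise ValueError(f"covariate column(s) entirely missing: {empty}")
    y = responses.loc[ids]
    keep = tab.notna().all(axis=1) & y.notna()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("complete-case rule dropped %d of %d subjects", n_drop, len(ids))
    tab, y = tab.loc[keep], y.loc[keep]

    grouped_cols = {c for members in dummy_groups.values() for c in members}
    specs: list[CovariateSpec] = []
    for gname, members in dummy_groups.items():
        present = [c for c in members if c in tab.columns]
        if present:
            specs.append(
                CovariateSpec(gname, "dummy_group", forced=gname in forced,
                              group_members=tuple(present))
            )
    for c in tab.columns:
        if c in grouped_cols:
            continue
        vals = tab[c].astype(float)
        nuniq = vals.nunique()
        kind = "indicator" if nuniq <= 2 else "continuous"
        if kind == "continuous" and standardize:
            sd = vals.std(ddof=1)
            if sd > 0:
                tab[c] = (vals - vals.mean()) / sd
        specs.append(CovariateSpec(c, kind, forced=c in forced))
    return y.astype(float), tab.astype(float), specs


def prune_collinear(
    table: pd.DataFrame,
    specs: list[CovariateSpec],
    outcome: pd.Series,
    threshold: float = 0.5,
    raw_scores: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[CovariateSpec], pd.DataFrame]:
    """Iteratively drop one of each collinear covariate pair.

    Pairwise Pearson |r| is computed over the selectable units — plain
    columns directly, dummy groups summarized by their raw 0–4 score
    column (``raw_scores``) when available, else the group's first
    indicator.  Of an offending pair, the unit whose |correlation| with
    the outcome is weaker is dropped; forced units are never dropped
    (two forced units above threshold are both kept, with a warning).
    Iterates until no pair exceeds the threshold; returns the pruned
    table, surviving specs, and a log of drops with both r values.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")

    def _summary(spec: CovariateSpec) -> np.ndarray:
        if spec.kind == "dummy_group":
            if raw_scores is not None and spec.name in raw_scores.columns:
                return raw_scores.loc[table.index, spec.name].astype(float).values
            return table[spec.group_members[0]].values
        return table[spec.name].values

    specs = list(specs)
    by_name = {s.name: s for s in specs}
    yv = outcome.values.astype(float)
    drops: list[tuple[str, str, float, float, float]] = []
    warned_forced: set[tuple[str, str]] = set()
    while len(specs) >= 2:
        cols = {s.name: _summary(s) for s in specs}
        names = list(cols)
        mat = np.corrcoef(np.column_stack([cols[n] for n in names]), rowvar=False)
        # worst offending pair with at least one removable member
        worst, pair = 0.0, None
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = abs(mat[i, j])
                if r <= threshold:
                    continue
                a, b = names[i], names[j]
                if by_name[a].forced and by_name[b].forced:
                    if (a, b) not in warned_forced:
                        logger.warning(
                            "forced covariates %s and %s collinear (|r|=%.3f); keeping both",
                            a, b, r,
                        )
                        warned_forced.add((a, b))
                    continue
                if r > worst:
                    worst, pair = r, (a, b)
        if pair is None:
            break
        a, b = pair
        sa, sb = by_name[a], by_name[b]
        r_a = abs(np.corrcoef(cols[a], yv)[0, 1])
        r_b = abs(np.corrcoef(cols[b], yv)[0, 1])
        if sa.forced:
            victim, kept, r_v, r_k = sb, sa, r_b, r_a
        elif sb.forced:
            victim, kept, r_v, r_k = sa, sb, r_a, r_b
        elif r_a < r_b:
            victim, kept, r_v, r_k = sa, sb, r_a, r_b
        else:
            victim, kept, r_v, r_k = sb, sa, r_b, r_a
        drops.append((victim.name, kept.name, worst, r_v, r_k))
        specs = [s for s in specs if s.name != victim.name]
        logger.info("dropped %s (|r|=%.3f with %s)", victim.name, worst, kept.name)
    kept_cols = [c for s in specs for c in s.columns]
    log = pd.DataFrame(drops, columns=["dropped", "collinear_with", "pair_r",
                                       "dropped_outcome_r", "kept_outcome_r"])
    return table[kept_cols], specs, log


@dataclass
class SelectionStep:
    removed: str
    bic_before: float
    bic_after: float


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.removed, s.bic_before, s.bic_after) for s in self.steps],
            columns=["removed", "bic_before", "bic_after"],
        )


def backward_select(
    y: pd.Series, table: pd.DataFrame, specs: list[CovariateSpec]
) -> tuple[FitResult, SelectionTrace, list[CovariateSpec]]:
    """Greedy backward elimination on BIC around forced covariates.

    At each step every non-forced unit (column or whole dummy group) is
    tentatively removed and the model refit; the removal giving the
    largest BIC reduction (ties broken by unit name) is committed.
    Stops when no removal reduces BIC.
    """
    active = list(specs)

    def _fit(units: list[CovariateSpec]) -> FitResult:
        cols = [c for s in units for c in s.columns]
        return fit_linear(y, table[cols])

    current = _fit(active)
    steps: list[SelectionStep] = []
    while True:
        candidates = sorted((s for s in active if not s.forced), key=lambda s: s.name)
        if not candidates:
            break
        best: tuple[float, CovariateSpec, FitResult] | None = None
        for spec in candidates:
            trial = [s for s in active if s is not spec]
            fit = _fit(trial)
            if best is None or fit.bic < best[0] - 1e-12:
                best = (fit.bic, spec, fit)
        assert best is not None
        if best[0] < current.bic:
            steps.append(SelectionStep(best[1].name, current.bic, best[0]))
            active = [s for s in active if s is not best[1]]
            current = best[2]
        else:
            break
    return current, SelectionTrace(steps), active
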