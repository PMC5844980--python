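"""PERMANOVA (distance-based multivariate ANOVA) with sequential sums of
squares, permutation p-values and a screen -> complex -> reduced model
selection protocol.

The distance matrix D is Gower-centred, G = -1/2 J D^2 J with
J = I - 11'/n; model terms, in the order given, contribute sequential
(Type-I) sums of squares through projection matrices built from their
design columns (categorical variables expand to centred dummies,
interactions to products of centred columns).  The pseudo-F of a term is
(SS_term/df_term)/(SS_res/df_res), R^2 = SS_term/SS_total, and p-values
come from permuting the rows/columns of D jointly with the add-one rule,
so p >= 1/(B+1).

On a univariate response with squared Euclidean ... i.e. plain Euclidean
distances, the one-factor pseudo-F reduces algebraically to the classical
one-way ANOVA F; the test suite asserts this identity to 1e-10.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_RANK_TOL = 1e-9


def _expand_variable(metadata: pd.DataFrame, name: str) -> np.ndarray:
    col = metadata[name]
    if col.isna().any():
        raise ValueError(f"missing metadata values in term {name!r}")
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(col.astype(str)).sort_index(axis=1)
        x = dummies.to_numpy(dtype=float)
    else:
        x = col.to_numpy(dtype=float)[:, None]
    return x - x.mean(axis=0)


def _expand_term(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Centred design columns for a term; 'a:b' = products of centred
    columns of a and b."""
    parts = term.split(":")
    x = _expand_variable(metadata, parts[0])
    for p in parts[1:]:
        y = _expand_variable(metadata, p)
        x = np.einsum("ni,nj->nij", x, y).reshape(len(x), -1)
        x = x - x.mean(axis=0)
    return x


def _orthonormal_increment(basis: np.ndarray | None, cols: np.ndarray):
    """Orthonormal basis of the span added by ``cols`` beyond ``basis``."""
    x = cols.copy()
    if basis is not None and basis.shape[1]:
        x = x - basis @ (basis.T @ x)
    if x.size == 0:
        return np.zeros((cols.shape[0], 0))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    keep = s > _RANK_TOL * max(1.0, s[0] if len(s) else 1.0)
    return u[:, keep]


def gower_center(dmat) -> np.ndarray:
    d = np.asarray(dmat, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d**2) @ j


def permanova(
    dmat,
    metadata: pd.DataFrame,
    terms: list[str],
    permutations: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sequential-SS PERMANOVA table for ``terms`` in the order given.

    ``dmat`` may be a DataFrame (ids must match ``metadata.index``) or an
    array aligned with ``metadata`` rows.  Returns a table with one row
    per term plus Residual and Total rows and columns Df, SumOfSquares,
    MeanSquares, F, R2, p.
    """
    if isinstance(dmat, pd.DataFrame):
        ids = list(dmat.index)
        metadata = metadata.loc[ids]
        d = dmat.to_numpy(dtype=float)
    else:
        d = np.asarray(dmat, dtype=float)
        if len(metadata) != d.shape[0]:
            raise ValueError("metadata does not match distance matrix")
    if not terms:
        raise ValueError("at least one model term required")
    g = gower_center(d)
    n = g.shape[0]
    ss_total = float(np.trace(g))

    bases: list[np.ndarray] = []
    dfs: list[int] = []
    full = None
    for term in terms:
        cols = _expand_term(metadata, term)
        inc = _orthonormal_increment(full, cols)
        if inc.shape[1] < cols.shape[1]:
            rank_drop = cols.shape[1] - inc.shape[1]
            # dummy expansions always lose one column to the intercept;
            # warn only beyond that
            if rank_drop > 1 or cols.shape[1] == 1:
                log.debug("term %s rank-deficient by %d", term, rank_drop)
        if inc.shape[1] == 0:
            warnings.warn(f"term {term!r} adds no degrees of freedom")
        bases.append(inc)
        dfs.append(inc.shape[1])
        full = inc if full is None else np.hstack([full, inc])

    df_model = sum(dfs)
    df_res = n - 1 - df_model
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_ss(gm: np.ndarray) -> np.ndarray:
        return np.array(
            [
                float(np.trace(b.T @ gm @ b)) if b.shape[1] else 0.0
                for b in bases
            ]
        )

    ss = term_ss(g)
    ss_res = ss_total - ss.sum()
    ms_res = ss_res / df_res
    f_obs = np.array(
        [
            (ss[k] / dfs[k]) / ms_res if dfs[k] else np.nan
            for k in range(len(terms))
        ]
    )

    pvals = np.full(len(terms), np.nan)
    if permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(terms))
        idx = np.arange(n)
        for _ in range(permutations):
            p = rng.permutation(idx)
            gp = g[np.ix_(p, p)]
            ssp = term_ss(gp)
            resp = ss_total - ssp.sum()
            msr = resp / df_res
            for k in range(len(terms)):
                if dfs[k]:
                    fp = (ssp[k] / dfs[k]) / msr
                    if fp >= f_obs[k] - 1e-12:
                        exceed[k] += 1
        pvals = (exceed + 1.0) / (permutations + 1.0)

    rows = []
    for k, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "Df": dfs[k],
                "SumOfSquares": ss[k],
                "MeanSquares": ss[k] / dfs[k] if dfs[k] else np.nan,
                "F": f_obs[k],
                "R2": ss[k] / ss_total,
                "p": pvals[k],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "Df": df_res,
            "SumOfSquares": ss_res,
            "MeanSquares": ms_res,
            "F": np.nan,
            "R2": ss_res / ss_total,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "Df": n - 1,
            "SumOfSquares": ss_total,
            "MeanSquares": np.nan,
            "F": np.nan,
            "R2": 1.0,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")


@dataclass
class ModelSelectionResult:
    screen: pd.DataFrame  # univariate + pairwise-interaction screen
    complex_model: pd.DataFrame | None
    reduced_model: pd.DataFrame | None
    complex_terms: list[str]
    reduced_terms: list[str]


def permanova_model_selection(
    dmat,
    metadata: pd.DataFrame,
    candidates: list[str],
    screen_alpha: float = 0.2,
    final_alpha: float = 0.05,
    permutations: int = 9999,
    seed: int | None = None,
    test_interactions: bool = True,
) -> ModelSelectionResult:
    """Three-stage variable selection on a beta-diversity matrix.

    Stage 1 screens every candidate univariately and (optionally) every
    variable pair's interaction term; survivors are the terms with
    p < ``screen_alpha``.  Stage 2 fits the complex model containing all
    surviving main effects (plus mains contained in surviving
    interactions) and surviving interactions.  Stage 3 retains the terms
    significant at ``final_alpha`` in the complex model (a main effect is
    also retained whenever a retained interaction contains it) and refits
    that reduced model.
    """
    rng = np.random.default_rng(seed)

    def child_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    screen_rows = []
    surv_main: list[str] = []
    for v in candidates:
        tab = permanova(dmat, metadata, [v], permutations, child_seed())
        p = float(tab.loc[v, "p"])
        screen_rows.append({"term": v, "kind": "main", "p": p})
        if p < screen_alpha:
            surv_main.append(v)
    surv_inter: list[str] = []
    if test_interactions:
        for v, w in itertools.combinations(candidates, 2):
            term = f"{v}:{w}"
            tab = permanova(dmat, metadata, [v, w, term], permutations, child_seed())
            p = float(tab.loc[term, "p"])
            screen_rows.append({"term": term, "kind": "interaction", "p": p})
            if p < screen_alpha:
                surv_inter.append(term)
    screen = pd.DataFrame(screen_rows).set_index("term")

    mains = [
        v
        for v in candidates
        if v in surv_main or any(v in t.split(":") for t in surv_inter)
    ]
    complex_terms = mains + surv_inter
    if not complex_terms:
        log.warning("no candidate survived the %.2f screen", screen_alpha)
        return ModelSelectionResult(screen, None, None, [], [])
    complex_model = permanova(dmat, metadata, complex_terms, permutations, child_seed())

    sig = [
        t
        for t in complex_terms
        if float(complex_model.loc[t, "p"]) < final_alpha
    ]
    keep_inter = [t for t in sig if ":" in t]
    keep_main = [
        v
        for v in mains
        if v in sig or any(v in t.split(":") for t in keep_inter)
    ]
    reduced_terms = keep_main + keep_inter
    reduced_model = (
        permanova(dmat, metadata, reduced_terms, permutations, child_seed())
        if reduced_terms
        else None
    )
    return ModelSelectionResult(
        screen=screen,
        complex_model=complex_model,
        reduced_model=reduced_model,
        complex_terms=complex_terms,
        reduced_terms=reduced_terms,
    )
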