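"""Inferential statistics for the cohort analysis.

Covers the association test between enterotype and diet group (Pearson
chi-square with Cramér's V), library-size-adjusted ANOVA with
Tukey-Kramer pairwise comparisons for alpha diversity, Kruskal-Wallis
group tests with Benjamini-Hochberg FDR control for per-taxon screens,
Spearman correlations, the Mantel test between nutrient and microbiota
distances, and the macro-nutrient energy summary (9/4/4 kcal per gram of
fat/protein/carbohydrate against the 30/15/55 guideline split).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel
from statsmodels.stats.multitest import multipletests


def chi_square_cramers_v(table) -> dict:
    """Pearson chi-square (no continuity correction) and Cramér's V.

    ``table`` is an r x c contingency table of counts.  V =
    sqrt(chi2 / (n (min(r, c) - 1))).  Zero row/column marginals fail
    explicitly.
    """
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    n = t.sum()
    v = float(np.sqrt(chi2 / (n * (min(t.shape) - 1))))
    return {"chi2": float(chi2), "df": int(df), "p": float(p), "cramers_v": v}


@dataclass
class AnovaTukeyResult:
    f: float
    p: float
    anova_table: pd.DataFrame
    pairwise: pd.DataFrame  # estimate, lower, upper, p_adj per group pair
    mse: float
    df_resid: int


def anova_tukey(
    values,
    groups,
    covariate=None,
    interaction: bool = False,
    alpha: float = 0.05,
) -> AnovaTukeyResult:
    """One-way ANOVA with optional covariate adjustment and Tukey HSD.

    With a covariate (e.g. library size) the group effect is the
    sequential F after the covariate enters first; ``interaction`` adds a
    group x covariate term after the group term.  Pairwise comparisons
    use the Tukey-Kramer studentized-range procedure for unequal group
    sizes; estimates are differences of raw group means.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": np.asarray(groups)})
    if df.groupby("g")["y"].count().min() < 2:
        raise ValueError("every group needs at least two observations")
    levels = sorted(df["g"].unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two groups")
    # sequential (Type-I) decomposition with the covariate entering first:
    # intercept [-> covariate] -> group [-> group x covariate]
    y = df["y"].to_numpy()
    n = len(y)
    dummies = pd.get_dummies(df["g"], drop_first=True).to_numpy(dtype=float)
    blocks: list[tuple[str, np.ndarray]] = [("Intercept", np.ones((n, 1)))]
    if covariate is not None:
        x = np.asarray(covariate, dtype=float)
        blocks.append(("covariate", x[:, None]))
    blocks.append(("group", dummies))
    if covariate is not None and interaction:
        blocks.append(("group:covariate", dummies * x[:, None]))

    rows = []
    design = None
    sse = {}
    for name, cols in blocks:
        design = cols if design is None else np.hstack([design, cols])
        resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        sse[name] = float((resid**2).sum())
    df_resid = int(n - design.shape[1])
    mse = sse[blocks[-1][0]] / df_resid
    names = [b[0] for b in blocks]
    for prev, cur, ncols in zip(names, names[1:], [b[1].shape[1] for b in blocks[1:]]):
        ss = sse[prev] - sse[cur]
        fstat = (ss / ncols) / mse
        rows.append(
            {
                "term": cur,
                "df": ncols,
                "sum_sq": ss,
                "mean_sq": ss / ncols,
                "F": fstat,
                "PR(>F)": float(sps.f.sf(fstat, ncols, df_resid)),
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_resid,
            "sum_sq": sse[names[-1]],
            "mean_sq": mse,
            "F": np.nan,
            "PR(>F)": np.nan,
        }
    )
    at = pd.DataFrame(rows).set_index("term")
    f = float(at.loc["group", "F"])
    p = float(at.loc["group", "PR(>F)"])

    means = df.groupby("g")["y"].mean()
    sizes = df.groupby("g")["y"].count()
    q_crit = sps.studentized_range.ppf(1 - alpha, k, df_resid)
    rows = []
    for i in range(k):
        for j in range(i):
            a, b = levels[i], levels[j]  # report later-vs-earlier level
            est = means[a] - means[b]
            se = np.sqrt(mse / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
            q = abs(est) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_resid))
            hw = q_crit * se
            rows.append(
                {
                    "contrast": f"{a} vs. {b}",
                    "estimate": est,
                    "lower": est - hw,
                    "upper": est + hw,
                    "p_adj": p_adj,
                }
            )
    return AnovaTukeyResult(
        f=f,
        p=p,
        anova_table=at,
        pairwise=pd.DataFrame(rows).set_index("contrast"),
        mse=mse,
        df_resid=df_resid,
    )


def kruskal_wallis(values, groups) -> dict:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value."""
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": np.asarray(groups)})
    samples = [sub["y"].to_numpy() for _, sub in df.groupby("g")]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(df["y"].to_numpy()) == 0:  # all values identical
        return {"H": 0.0, "df": len(samples) - 1, "p": 1.0}
    h, p = sps.kruskal(*samples)
    return {"H": float(h), "df": len(samples) - 1, "p": float(p)}


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y) -> dict:
    """Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined")
        return {"rho": float("nan"), "p": float("nan")}
    rho, p = sps.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}


def mantel(
    d1,
    d2,
    permutations: int = 9999,
    seed: int | None = None,
    method: str = "pearson",
) -> dict:
    """Mantel test between two distance matrices (same ids, same order).

    The statistic is the correlation of the upper-triangle entries; the
    one-sided p-value permutes one matrix's rows/columns jointly with the
    add-one rule, so p >= 1/(permutations + 1).
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape or a.shape[0] < 3:
        raise ValueError("matrices must match and have size >= 3")
    r, p, _ = _skbio_mantel(
        DistanceMatrix(a),
        DistanceMatrix(b),
        method=method,
        permutations=permutations,
        alternative="greater",
        seed=seed,
    )
    return {"r": float(r), "p": float(p)}


def differential_abundance(
    counts: pd.DataFrame, groups: pd.Series, fdr_alpha: float = 0.05
) -> pd.DataFrame:
    """Per-taxon Kruskal-Wallis across groups with BH FDR (one family).

    ``counts`` is taxa x samples (counts or relative abundances);
    ``groups`` maps sample id -> group label.
    """
    groups = groups.loc[counts.columns]
    rows = []
    for taxon in counts.index:
        res = kruskal_wallis(counts.loc[taxon].to_numpy(), groups.to_numpy())
        rows.append({"taxon": taxon, "H": res["H"], "p": res["p"]})
    out = pd.DataFrame(rows).set_index("taxon")
    out["p_adj"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < fdr_alpha
    return out


KCAL_PER_GRAM = {"fat": 9.0, "protein": 4.0, "carbohydrate": 4.0}
GUIDELINE_PCT = {"fat": 30.0, "protein": 15.0, "carbohydrate": 55.0}


def macro_summary(
    nutrients: pd.DataFrame,
    fat_col: str = "fat_g",
    protein_col: str = "protein_g",
    carb_col: str = "carbohydrate_g",
) -> pd.DataFrame:
    """Energy summary per sample from macro-nutrient grams per day.

    kcal = 9*fat + 4*protein + 4*carbohydrate; percentages of total kcal
    per macro plus deltas against the 30/15/55 guideline split.  Samples
    with zero total energy get NaN percentages and a warning.
    """
    f = nutrients[fat_col].astype(float)
    p = nutrients[protein_col].astype(float)
    c = nutrients[carb_col].astype(float)
    if (pd.concat([f, p, c], axis=1) < 0).any().any():
        raise ValueError("macro-nutrient grams must be non-negative")
    kcal = KCAL_PER_GRAM["fat"] * f + KCAL_PER_GRAM["protein"] * p + KCAL_PER_GRAM["carbohydrate"] * c
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_fat = np.where(kcal > 0, 100.0 * KCAL_PER_GRAM["fat"] * f / kcal, np.nan)
        pct_pro = np.where(kcal > 0, 100.0 * KCAL_PER_GRAM["protein"] * p / kcal, np.nan)
        pct_car = np.where(kcal > 0, 100.0 * KCAL_PER_GRAM["carbohydrate"] * c / kcal, np.nan)
    if (kcal == 0).any():
        warnings.warn("samples with zero total energy: percentages undefined")
    return pd.DataFrame(
        {
            "kcal_total": kcal,
            "pct_fat": pct_fat,
            "pct_protein": pct_pro,
            "pct_carbohydrate": pct_car,
            "delta_fat": pct_fat - GUIDELINE_PCT["fat"],
            "delta_protein": pct_pro - GUIDELINE_PCT["protein"],
            "delta_carbohydrate": pct_car - GUIDELINE_PCT["carbohydrate"],
        },
        index=nutrients.index,
    )
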