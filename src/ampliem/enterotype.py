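"""Enterotype assignment of gut community profiles.

Samples are stratified into three community types labelled by their
prevalent family (Bacteroidaceae, Prevotellaceae or Ruminococcaceae).
The default method clusters family-level relative-abundance profiles by
partition-around-medoids (PAM) on the root Jensen-Shannon divergence,
after replacing zeros with a pseudo-proportion of 1e-6 and
renormalising; each cluster is then labelled by whichever of the three
marker families has the highest mean abundance inside it.  The
alternative ``dominant_family`` method simply takes the per-sample argmax
over the three marker families.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

ENTEROTYPE_FAMILIES = ("Bacteroidaceae", "Prevotellaceae", "Ruminococcaceae")


def jsd_matrix(profiles: pd.DataFrame, pseudo: float = 1e-6) -> pd.DataFrame:
    """Pairwise root Jensen-Shannon divergence between profile rows.

    Zeros are replaced by ``pseudo`` and rows renormalised so the
    divergence is finite everywhere.
    """
    x = profiles.to_numpy(dtype=float)
    x = np.where(x <= 0, pseudo, x)
    x = x / x.sum(axis=1, keepdims=True)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jensenshannon(x[i], x[j])
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def pam(dmat: pd.DataFrame, k: int, seed: int | None = None, max_iter: int = 100):
    """Partition around medoids on a precomputed distance matrix.

    BUILD picks medoids greedily (first the point minimising total
    distance, then the point giving the largest cost reduction); SWAP
    exchanges medoid/non-medoid pairs while the total cost drops.  The
    seed only breaks exact cost ties, so results are reproducible.
    """
    d = dmat.to_numpy(dtype=float)
    n = d.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of samples")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(0, 1e-12, size=n)  # deterministic tie-break only

    medoids = [int(np.argmin(d.sum(axis=1) + jitter))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.array(
            [
                np.maximum(current - d[:, c], 0).sum() if c not in medoids else -1.0
                for c in range(n)
            ]
        )
        medoids.append(int(np.argmax(gains + jitter)))

    def cost(meds):
        return d[:, meds].min(axis=1).sum()

    best = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for mi, m in enumerate(list(medoids)):
            for c in range(n):
                if c in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = c
                tc = cost(trial)
                if tc < best - 1e-12:
                    medoids, best = trial, tc
                    improved = True
        if not improved:
            break
    labels = np.argmin(d[:, medoids], axis=1)
    return labels, [dmat.index[m] for m in medoids]


def enterotype_assign(
    family_profiles: pd.DataFrame,
    method: str = "pam_jsd",
    k: int = 3,
    seed: int | None = None,
    pseudo: float = 1e-6,
) -> pd.DataFrame:
    """Assign an enterotype to each sample (rows = samples, columns =
    family relative abundances summing to 1).

    Returns a DataFrame with columns ``cluster`` (PAM cluster index, or
    -1 for dominant_family) and ``enterotype`` (one of the three marker
    families).  With ``pam_jsd`` a tie in a cluster's mean marker-family
    abundance raises, demanding manual labels.
    """
    missing = [f for f in ENTEROTYPE_FAMILIES if f not in family_profiles.columns]
    if missing:
        raise ValueError(f"profiles lack marker families: {missing}")
    if method == "dominant_family":
        sub = family_profiles[list(ENTEROTYPE_FAMILIES)]
        label = sub.idxmax(axis=1)
        return pd.DataFrame(
            {"cluster": -1, "enterotype": label}, index=family_profiles.index
        )
    if method != "pam_jsd":
        raise ValueError(f"unknown method {method!r}")
    d = jsd_matrix(family_profiles, pseudo=pseudo)
    labels, _ = pam(d, k=k, seed=seed)
    cluster_label = {}
    for c in range(k):
        members = family_profiles.iloc[labels == c]
        means = members[list(ENTEROTYPE_FAMILIES)].mean()
        top = means[means == means.max()]
        if len(top) > 1:
            raise ValueError(
                f"cluster {c}: tie between marker families {list(top.index)}; "
                "manual labels required"
            )
        cluster_label[c] = top.index[0]
    return pd.DataFrame(
        {
            "cluster": labels,
            "enterotype": [cluster_label[c] for c in labels],
        },
        index=family_profiles.index,
    )


def enterotype_contingency(
    assignments: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Enterotype x diet-group contingency table of sample counts."""
    groups = groups.loc[assignments.index]
    return pd.crosstab(assignments["enterotype"], groups)
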