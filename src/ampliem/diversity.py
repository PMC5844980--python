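"""Alpha diversity indices, beta diversity distances, UniFrac, PCoA,
hierarchical clustering.

Conventions: Shannon entropy is in nats and evenness divides by
``ln(S_obs)`` (the index's maximum); Chao1 defaults to the
bias-corrected form ``S + F1(F1-1)/(2(F2+1))`` so doubleton-free samples
stay finite; Simpson is reported as the complement ``1 - sum(p^2)``
alongside the inverse form.  The Canberra distance is averaged over the
taxa with a nonzero pair sum (so it lies in [0, 1]).  UniFrac (weighted
normalized and unweighted) is computed on a supplied rooted tree with
branch lengths; tree inference is out of scope.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode


@dataclass
class AlphaDiversity:
    richness: int
    chao1: float
    shannon: float
    simpson: float
    inverse_simpson: float
    evenness: float  # NaN when S_obs <= 1


def alpha_diversity(counts, bias_corrected: bool = True) -> AlphaDiversity:
    """Alpha indices for one sample of non-negative integer counts."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    n = x.sum()
    if n == 0:
        warnings.warn("all-zero sample: alpha diversity undefined")
        nan = float("nan")
        return AlphaDiversity(0, nan, nan, nan, nan, nan)
    nz = x[x > 0]
    s_obs = int(len(nz))
    f1 = int((nz == 1).sum())
    f2 = int((nz == 2).sum())
    if bias_corrected:
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        chao1 = s_obs + (f1 * f1 / (2.0 * f2) if f2 > 0 else math.inf if f1 else 0.0)
    p = nz / n
    shannon = float(-(p * np.log(p)).sum())
    sum_p2 = float((p**2).sum())
    evenness = shannon / math.log(s_obs) if s_obs > 1 else float("nan")
    return AlphaDiversity(
        richness=s_obs,
        chao1=float(chao1),
        shannon=shannon,
        simpson=1.0 - sum_p2,
        inverse_simpson=1.0 / sum_p2,
        evenness=evenness,
    )


def alpha_table(counts: pd.DataFrame, bias_corrected: bool = True) -> pd.DataFrame:
    """Alpha indices per sample for a counts table (OTUs x samples)."""
    rows = {
        s: vars(alpha_diversity(counts[s].to_numpy(), bias_corrected))
        for s in counts.columns
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def _bray_curtis(x, y):
    denom = (x + y).sum()
    if denom == 0:
        return np.nan
    return np.abs(x - y).sum() / denom


def _canberra(x, y):
    s = x + y
    nz = s > 0
    if not nz.any():
        return np.nan
    return float((np.abs(x - y)[nz] / s[nz]).sum() / nz.sum())


def beta_distance(profiles, metric: str = "bray_curtis") -> pd.DataFrame:
    """Pairwise distances between rows of ``profiles`` (samples x taxa).

    Metrics: ``bray_curtis`` = sum|x-y| / sum(x+y); ``canberra`` =
    mean of |x-y|/(x+y) over taxa with a nonzero pair sum.  A pair of
    all-zero profiles yields NaN with a warning.
    """
    fn = {"bray_curtis": _bray_curtis, "canberra": _canberra}.get(metric)
    if fn is None:
        raise ValueError(f"unknown metric {metric!r}")
    profiles = pd.DataFrame(profiles)
    ids = list(profiles.index)
    x = profiles.to_numpy(dtype=float)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(x[i], x[j])
    if np.isnan(d).any():
        warnings.warn("some sample pairs had all-zero profiles; distances are NaN")
    return pd.DataFrame(d, index=ids, columns=ids)


def read_tree(source) -> TreeNode:
    """Read a newick tree from a path or string."""
    text = str(source)
    if "(" in text and ";" in text:
        return TreeNode.read(io.StringIO(text))
    return TreeNode.read(text)


def unifrac(
    tree: TreeNode,
    x,
    y,
    taxa: list[str],
    weighted: bool = False,
    normalized: bool = True,
) -> float:
    """UniFrac distance between two communities on a supplied tree.

    Unweighted: branch length unique to one community's leaf set over the
    total branch length spanned by either.  Weighted: branch lengths
    weighted by the difference in the fraction of each community's reads
    descending from the branch; the normalized variant (default) lies in
    [0, 1].  Fails explicitly when nonzero taxa are missing from the tree.
    """
    leaf_names = {t.name for t in tree.tips()}
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    present = [t for t, xv, yv in zip(taxa, x, y) if (xv > 0 or yv > 0)]
    missing = [t for t in present if t not in leaf_names]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    tx, ty = x.sum(), y.sum()
    if tx == 0 or ty == 0:
        warnings.warn("empty community: UniFrac undefined")
        return float("nan")
    xv = {t: v / tx for t, v in zip(taxa, x)}
    yv = {t: v / ty for t, v in zip(taxa, y)}
    # postorder branch walk: fraction of each community under every branch
    px: dict[int, float] = {}
    py: dict[int, float] = {}
    num = den = 0.0
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            a = xv.get(node.name, 0.0)
            b = yv.get(node.name, 0.0)
        else:
            a = sum(px[id(c)] for c in node.children)
            b = sum(py[id(c)] for c in node.children)
        px[id(node)], py[id(node)] = a, b
        length = node.length or 0.0
        if weighted:
            num += length * abs(a - b)
            den += length * (a + b)
        else:
            if a > 0 or b > 0:
                den += length
                if (a > 0) != (b > 0):
                    num += length
    if weighted and not normalized:
        return float(num)
    if den == 0:
        return 0.0
    return float(num / den)


def unifrac_matrix(
    counts: pd.DataFrame, tree: TreeNode, weighted: bool = False,
    normalized: bool = True,
) -> pd.DataFrame:
    """Pairwise UniFrac over the columns (samples) of a counts table."""
    taxa = list(counts.index)
    ids = list(counts.columns)
    n = len(ids)
    d = np.zeros((n, n))
    x = counts.to_numpy(dtype=float).T
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = unifrac(
                tree, x[i], x[j], taxa, weighted=weighted, normalized=normalized
            )
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(dmat: pd.DataFrame) -> PcoaResult:
    """Principal coordinate analysis by Gower double centering.

    Negative eigenvalues (possible for non-Euclidean distances) are
    reported but excluded from the proportion-explained denominator and
    carry no coordinate axes.
    """
    d = np.asarray(dmat, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10 * max(1.0, abs(vals[0]))
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    ids = list(dmat.index) if isinstance(dmat, pd.DataFrame) else list(range(n))
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords, index=ids, columns=[f"PCo{i+1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=vals,
        proportion_explained=vals[pos] / vals[pos].sum(),
    )


def hclust(dmat: pd.DataFrame, method: str = "average") -> np.ndarray:
    """Agglomerative clustering linkage matrix (scipy format) with
    non-decreasing merge heights."""
    d = np.asarray(dmat, dtype=float)
    z = hierarchy.linkage(squareform(d, checks=False), method=method)
    return z
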