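"""Abundance-seeded EM clustering of dereplicated amplicons into OTUs.

Initialisation follows a four-step abundance-sum procedure:

(i)   for every sequence, sum the abundances of every *other* sequence
      within the clustering radius (default 3% distance, inclusive);
(ii)  sort sequences by that sum, descending;
(iii) walk the sorted list; each still-ungrouped sequence seeds a group
      and captures every ungrouped sequence at distance < radius
      (strict), until none remain;
(iv)  the seed of each group becomes its representative and every
      non-seed sequence is re-assigned to its nearest seed.

The EM refinement treats the seeds as centres of a finite mixture whose
component kernel decays exponentially with genetic distance,

    f(j | k)  proportional to  exp(-sigma * d(j, centre_k)),

with sigma = 250 by default, so a sequence 3% away from a centre has
kernel weight exp(-7.5) ~ 5.5e-4 relative to the centre itself — the 3%
radius behaves as a soft boundary.  The E-step computes abundance-weighted
responsibilities, the M-step updates mixing weights and moves each centre
to the medoid sequence minimising the responsibility-weighted distance sum
(centres therefore remain observed sequences and always have computable
taxonomy).  Components whose weight collapses are pruned; the weighted
log-likelihood is monitored and must never decrease.  Given the
initialisation the algorithm is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import DereplicatedSequence

log = logging.getLogger(__name__)


@dataclass
class InitGroups:
    """Ordered seed groups from the abundance-sum initialisation."""

    seeds: list[str]  # representative ids, in sort order
    members: dict[str, list[str]]  # seed id -> non-seed member ids
    neighbor_abundance: dict[str, int]  # step (i) sums

    def group_of(self) -> dict[str, str]:
        out = {}
        for seed in self.seeds:
            out[seed] = seed
            for m in self.members[seed]:
                out[m] = seed
        return out


@dataclass
class EmModel:
    centre_ids: list[str]
    weights: np.ndarray  # mixing proportions pi_k
    responsibilities: pd.DataFrame  # sequences x components
    sigma: float
    log_likelihood: list[float]
    converged: bool


@dataclass
class Otu:
    id: str
    representative: DereplicatedSequence
    members: list[DereplicatedSequence]
    total_abundance: int
    per_sample_counts: dict[str, int]


@dataclass
class OtuSet:
    otus: list[Otu]
    model: EmModel | None = None

    def __len__(self) -> int:
        return len(self.otus)

    @property
    def total_abundance(self) -> int:
        return sum(o.total_abundance for o in self.otus)


def initialize_groups(
    seqs: list[DereplicatedSequence],
    dmat: pd.DataFrame,
    threshold: float = 0.03,
    radius_inclusive: bool = True,
) -> InitGroups:
    """Abundance-sum seeding, steps (i)-(iv).

    ``radius_inclusive`` controls step (i) ("within" -> d <= threshold);
    step (iii) capture is always strict (d < threshold).
    """
    ids = [s.id for s in seqs]
    if set(ids) - set(dmat.index):
        raise ValueError("distance matrix does not cover all sequences")
    ab = {s.id: s.abundance for s in seqs}
    d = dmat.loc[ids, ids].to_numpy()
    a = np.array([ab[i] for i in ids], dtype=float)

    # (i) neighbour abundance sums, excluding self
    if radius_inclusive:
        close = d <= threshold
    else:
        close = d < threshold
    np.fill_diagonal(close, False)
    sums = close @ a

    # (ii) descending sort; ties -> higher own abundance, then id
    order = sorted(range(len(ids)), key=lambda i: (-sums[i], -a[i], ids[i]))

    # (iii) iterative capture
    grouped = np.zeros(len(ids), dtype=bool)
    seeds: list[int] = []
    capture: dict[int, list[int]] = {}
    for i in order:
        if grouped[i]:
            continue
        grouped[i] = True
        seeds.append(i)
        mem = [
            j
            for j in order
            if not grouped[j] and d[i, j] < threshold
        ]
        for j in mem:
            grouped[j] = True
        capture[i] = mem

    # (iv) regroup every non-seed to its nearest seed (ties -> earlier seed)
    members: dict[str, list[str]] = {ids[s]: [] for s in seeds}
    seed_arr = np.array(seeds)
    for i in range(len(ids)):
        if i in capture:
            continue
        dist_to_seeds = d[i, seed_arr]
        best = int(np.argmin(dist_to_seeds))  # argmin keeps earliest on ties
        members[ids[seeds[best]]].append(ids[i])
    return InitGroups(
        seeds=[ids[s] for s in seeds],
        members=members,
        neighbor_abundance={ids[i]: int(sums[i]) for i in range(len(ids))},
    )


def _log_likelihood(logpi, d_to_centres, sigma, a):
    # weighted log sum_k pi_k exp(-sigma d_jk)
    z = logpi[None, :] - sigma * d_to_centres
    m = z.max(axis=1)
    ll = m + np.log(np.exp(z - m[:, None]).sum(axis=1))
    return float((a * ll).sum())


def em_cluster(
    seqs: list[DereplicatedSequence],
    dmat: pd.DataFrame,
    init: InitGroups,
    sigma: float = 250.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune_weight: float = 1e-12,
) -> OtuSet:
    """Refine the seed groups by EM and return the final OTU set.

    Raises on empty initialisation; when ``max_iter`` is reached without
    the log-likelihood change dropping below ``tol`` the best model is
    returned with ``converged=False``.
    """
    if not init.seeds:
        raise ValueError("initialisation has no seed groups")
    ids = [s.id for s in seqs]
    idx = {sid: i for i, sid in enumerate(ids)}
    by_id = {s.id: s for s in seqs}
    d = dmat.loc[ids, ids].to_numpy()
    a = np.array([s.abundance for s in seqs], dtype=float)
    a_total = a.sum()

    centres = [idx[s] for s in init.seeds]
    pi = np.array(
        [
            sum(by_id[m].abundance for m in [s] + init.members[s])
            for s in init.seeds
        ],
        dtype=float,
    )
    pi = pi / pi.sum()

    ll_trace: list[float] = []
    converged = False
    z = None
    for _ in range(max_iter):
        dc = d[:, centres]
        logpi = np.log(pi)
        ll = _log_likelihood(logpi, dc, sigma, a)
        if ll_trace and ll < ll_trace[-1] - 1e-8:
            raise AssertionError("EM log-likelihood decreased")
        if ll_trace and abs(ll - ll_trace[-1]) < tol:
            ll_trace.append(ll)
            converged = True
            break
        ll_trace.append(ll)
        # E-step (record which centres the responsibilities refer to)
        e_centres = list(centres)
        logz = logpi[None, :] - sigma * dc
        logz -= logz.max(axis=1, keepdims=True)
        z = np.exp(logz)
        z /= z.sum(axis=1, keepdims=True)
        # M-step: weights
        pi = (a[:, None] * z).sum(axis=0) / a_total
        # prune collapsed components
        keep = pi >= prune_weight
        if not keep.all():
            z = z[:, keep]
            z /= z.sum(axis=1, keepdims=True)
            pi = pi[keep]
            pi /= pi.sum()
            centres = [c for c, k in zip(centres, keep) if k]
            e_centres = [c for c, k in zip(e_centres, keep) if k]
        # M-step: medoid centres (candidate = any sequence; ties -> earlier)
        w = a[:, None] * z  # n x K
        costs = d.T @ w  # candidate m x component k
        centres = [int(np.argmin(costs[:, k])) for k in range(len(centres))]

    if z is None:  # max_iter == 0 edge
        e_centres = list(centres)
        dc = d[:, centres]
        logz = np.log(pi)[None, :] - sigma * dc
        logz -= logz.max(axis=1, keepdims=True)
        z = np.exp(logz)
        z /= z.sum(axis=1, keepdims=True)
    if not converged:
        log.warning("EM did not converge in %d iterations", max_iter)

    # hard assignment: argmax z; ties -> larger pi, then earlier component
    order = np.lexsort((np.arange(len(pi)), -pi))
    rank = np.empty(len(pi), dtype=int)
    rank[order] = np.arange(len(pi))
    zr = z - 1e-15 * rank[None, :]  # infinitesimal preference for ranked ties
    hard = np.argmax(zr, axis=1)

    model = EmModel(
        centre_ids=[ids[c] for c in centres],
        weights=pi.copy(),
        responsibilities=pd.DataFrame(
            z, index=ids, columns=[ids[c] for c in e_centres]
        ),
        sigma=sigma,
        log_likelihood=ll_trace,
        converged=converged,
    )

    otus: list[Otu] = []
    for k, c in enumerate(centres):
        member_idx = np.nonzero(hard == k)[0]
        members = [seqs[i] for i in member_idx]
        if not members:
            continue
        per_sample: dict[str, int] = {}
        for s in members:
            for smp, cnt in s.per_sample_counts.items():
                per_sample[smp] = per_sample.get(smp, 0) + cnt
        otus.append(
            Otu(
                id=f"otu{k:04d}",
                representative=seqs[c],
                members=members,
                total_abundance=int(sum(s.abundance for s in members)),
                per_sample_counts=per_sample,
            )
        )
    # stable ids by descending abundance
    otus.sort(key=lambda o: (-o.total_abundance, o.representative.id))
    for i, o in enumerate(otus):
        o.id = f"otu{i:04d}"
    return OtuSet(otus=otus, model=model)


def cluster_sequences(
    seqs: list[DereplicatedSequence],
    dmat: pd.DataFrame,
    threshold: float = 0.03,
    sigma: float = 250.0,
    **em_kwargs,
) -> OtuSet:
    """Initialise and EM-refine in one call."""
    init = initialize_groups(seqs, dmat, threshold=threshold)
    return em_cluster(seqs, dmat, init, sigma=sigma, **em_kwargs)


def build_otu_table(otus: OtuSet, samples: list[str] | None = None):
    """Counts table (OTUs x samples) from an OTU set; see feature_table."""
    from .tables import OtuTable

    if samples is None:
        seen: dict[str, None] = {}
        for o in otus.otus:
            for s in o.per_sample_counts:
                seen.setdefault(s)
        samples = sorted(seen)
    rows = {
        o.id: [o.per_sample_counts.get(s, 0) for s in samples] for o in otus.otus
    }
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    counts = counts.loc[
        sorted(counts.index, key=lambda i: (-counts.loc[i].sum(), i))
    ]
    reps = {o.id: o.representative.sequence for o in otus.otus}
    return OtuTable(counts=counts.astype(int), representatives=reps)
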