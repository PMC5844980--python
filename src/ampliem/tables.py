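"""OTU table container, lineage filters, replicate selection, collapsing,
relative abundance and TMM normalization.

An :class:`OtuTable` holds an integer counts matrix (OTUs x samples), an
optional taxonomy frame (one column per rank, NaN past the deepest
assigned rank) and optional representative sequences.  All operations
return new objects; filters are idempotent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .taxonomy import RANKS, TaxonomyAssignment

log = logging.getLogger(__name__)


@dataclass
class OtuTable:
    counts: pd.DataFrame  # OTUs x samples, non-negative integers
    taxonomy: pd.DataFrame | None = None  # index: OTU id, columns: RANKS
    representatives: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.taxonomy is not None:
            missing = set(self.counts.index) - set(self.taxonomy.index)
            if missing:
                raise ValueError(f"taxonomy missing for OTUs: {sorted(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def with_taxonomy(self, assignments: dict[str, TaxonomyAssignment]) -> "OtuTable":
        rows = {}
        for oid in self.counts.index:
            lineage = assignments[oid].lineage if oid in assignments else ()
            rows[oid] = list(lineage) + [np.nan] * (len(RANKS) - len(lineage))
        tax = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
        return replace(self, taxonomy=tax)

    def subset_otus(self, otu_ids) -> "OtuTable":
        otu_ids = [o for o in self.counts.index if o in set(otu_ids)]
        tax = self.taxonomy.loc[otu_ids] if self.taxonomy is not None else None
        reps = (
            {o: self.representatives[o] for o in otu_ids if o in self.representatives}
            if self.representatives
            else None
        )
        return OtuTable(self.counts.loc[otu_ids], tax, reps)

    def subset_samples(self, sample_ids) -> "OtuTable":
        keep = [s for s in self.counts.columns if s in set(sample_ids)]
        return replace(self, counts=self.counts[keep])

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")

    @staticmethod
    def from_tsv(path) -> "OtuTable":
        return OtuTable(pd.read_csv(path, sep="\t", index_col=0))


def filter_taxa(
    table: OtuTable,
    remove_terms: tuple[str, ...] = ("mitochondria", "chloroplast"),
    allowed_domains: tuple[str, ...] = ("Bacteria",),
    remove_phyla: tuple[str, ...] = ("Cyanobacteria",),
    exclude_ids: tuple[str, ...] = (),
) -> tuple[OtuTable, dict[str, int]]:
    """Remove off-target OTUs from the table.

    Rules, applied in order with removal counts logged per rule:
    organelle lineages (any rank matching ``remove_terms``,
    case-insensitive), domains outside ``allowed_domains``, the listed
    phyla (chloroplast 16S interference), and an explicit id exclusion
    list (stand-in for OTUs removed after tree inspection).  Unassigned
    OTUs (empty lineage) are retained.
    """
    if table.taxonomy is None:
        raise ValueError("filter_taxa requires taxonomy")
    tax = table.taxonomy
    terms = {t.lower() for t in remove_terms}
    removed: dict[str, list] = {"organelle": [], "domain": [], "phylum": [], "excluded": []}
    keep = []
    excl = set(exclude_ids)
    for oid in table.counts.index:
        lineage = [str(v) for v in tax.loc[oid] if pd.notna(v)]
        low = {v.lower() for v in lineage}
        if oid in excl:
            removed["excluded"].append(oid)
        elif low & terms:
            removed["organelle"].append(oid)
        elif lineage and lineage[0] not in allowed_domains:
            removed["domain"].append(oid)
        elif len(lineage) > 1 and lineage[1] in remove_phyla:
            removed["phylum"].append(oid)
        else:
            keep.append(oid)
    counts = {k: len(v) for k, v in removed.items()}
    log.info("filter_taxa removals: %s", counts)
    return table.subset_otus(keep), counts


def select_replicates(
    table: OtuTable,
    replicate_pairs: dict[str, tuple[str, str]],
    on_inconsistent: str = "keep_larger",
) -> tuple[OtuTable, pd.DataFrame]:
    """Verify replicate consistency and keep one replicate per subject.

    For every subject the two technical replicates must be mutual nearest
    neighbours in the Bray-Curtis distance matrix of relative profiles
    (the hierarchical-clustering "always cluster together" check reduces
    to mutual nearest neighbourhood under average linkage).  On success
    the replicate with the larger library is retained and renamed to the
    subject id; failures are flagged and handled per ``on_inconsistent``
    ("keep_larger" or "drop").
    """
    from .diversity import beta_distance

    for subj, (r1, r2) in replicate_pairs.items():
        for r in (r1, r2):
            if r not in table.counts.columns:
                raise ValueError(f"subject {subj}: replicate {r} missing from table")
    rel = table.counts / table.counts.sum(axis=0)
    d = beta_distance(rel.T, metric="bray_curtis")
    lib = table.library_sizes
    rows = []
    kept_cols: dict[str, str] = {}
    dm = d.to_numpy().copy()
    np.fill_diagonal(dm, np.inf)
    nn = pd.Series(d.columns[np.argmin(dm, axis=1)], index=d.index)
    for subj, (r1, r2) in replicate_pairs.items():
        consistent = bool(nn[r1] == r2 and nn[r2] == r1)
        larger = r1 if lib[r1] >= lib[r2] else r2
        keep = larger if (consistent or on_inconsistent == "keep_larger") else None
        rows.append(
            {
                "subject": subj,
                "replicate_1": r1,
                "replicate_2": r2,
                "consistent": consistent,
                "kept": keep,
                "library_kept": int(lib[keep]) if keep else 0,
            }
        )
        if keep:
            kept_cols[keep] = subj
    report = pd.DataFrame(rows).set_index("subject")
    n_bad = int((~report["consistent"]).sum())
    if n_bad:
        log.warning("%d subjects failed replicate consistency", n_bad)
    out = replace(
        table,
        counts=table.counts[list(kept_cols)].rename(columns=kept_cols),
    )
    return out, report


def collapse_rank(table: OtuTable, rank: str) -> OtuTable:
    """Sum counts per lineage value at ``rank``.

    OTUs unassigned at that rank aggregate under their deepest assigned
    label, tagged with its rank, e.g. ``"Ruminococcaceae (family)"``;
    fully unassigned OTUs fall under ``"unassigned"``.  Counts are
    conserved exactly.
    """
    if table.taxonomy is None:
        raise ValueError("collapse_rank requires taxonomy")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    depth = RANKS.index(rank)
    labels = []
    for oid in table.counts.index:
        lineage = [str(v) for v in table.taxonomy.loc[oid] if pd.notna(v)]
        if len(lineage) > depth:
            labels.append(lineage[depth])
        elif lineage:
            labels.append(f"{lineage[-1]} ({RANKS[len(lineage) - 1]})")
        else:
            labels.append("unassigned")
    collapsed = table.counts.groupby(pd.Index(labels, name=rank)).sum()
    collapsed = collapsed.loc[
        sorted(collapsed.index, key=lambda i: (-collapsed.loc[i].sum(), i))
    ]
    return OtuTable(collapsed)


def relative_abundance(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions; zero-library samples dropped with a warning."""
    counts = table.counts if isinstance(table, OtuTable) else table
    lib = counts.sum(axis=0)
    empty = lib[lib == 0].index
    if len(empty):
        warnings.warn(f"dropping zero-library samples: {list(empty)}")
        counts = counts.drop(columns=empty)
        lib = lib.drop(empty)
    return counts / lib


@dataclass
class NormalizationFactors:
    """TMM output: composition factors (geometric mean 1, the trimmed
    mean-of-M-values sense) and depth-inclusive scaling factors
    (library size x composition factor, rescaled to geometric mean 1)."""

    composition_factor: pd.Series
    scaling_factor: pd.Series
    reference_sample: str

    @property
    def factors(self) -> pd.Series:
        return self.scaling_factor


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a):
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return np.nan
    o = obs[both] / n_obs
    r = ref[both] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # delta-method precision weights
    w = (n_obs - obs[both]) / (n_obs * obs[both]) + (n_ref - ref[both]) / (
        n_ref * ref[both]
    )
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return np.nan
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 2.0**f


def tmm_factors(
    table: OtuTable | pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed mean of M-values normalization.

    The reference is the sample whose upper quartile of nonzero relative
    counts is closest to the mean upper quartile.  Per sample, log-ratios
    (M) and average log-abundances (A) over OTUs nonzero in both the
    sample and the reference are doubly trimmed (30% on M, 5% on A) and
    the factor is 2 to the precision-weighted mean of the retained M.
    A sample sharing no nonzero OTU with the reference gets factor 1 with
    a warning.
    """
    counts = table.counts if isinstance(table, OtuTable) else table
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    uq = np.array(
        [
            np.quantile(col[col > 0] / n, 0.75) if (col > 0).any() else 0.0
            for col, n in zip(y.T, lib)
        ]
    )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.ones(counts.shape[1])
    for s in range(counts.shape[1]):
        if s == ref_idx:
            continue
        fs = _tmm_pair(y[:, s], y[:, ref_idx], lib[s], lib[ref_idx], trim_m, trim_a)
        if np.isnan(fs):
            warnings.warn(
                f"sample {counts.columns[s]} shares no nonzero OTU with the "
                "reference; TMM factor set to 1"
            )
            fs = 1.0
        f[s] = fs
    comp = f / np.exp(np.mean(np.log(f)))
    scaling = lib * comp
    scaling = scaling / np.exp(np.mean(np.log(scaling)))
    return NormalizationFactors(
        composition_factor=pd.Series(comp, index=counts.columns),
        scaling_factor=pd.Series(scaling, index=counts.columns),
        reference_sample=str(counts.columns[ref_idx]),
    )


def core_shared_unique(
    table: OtuTable,
    groups: pd.Series,
    prevalence: float = 0.90,
) -> dict:
    """Per-group core OTUs, 7-region Venn of detected sets, core-sharing check.

    Detection is count >= 1; an OTU is in a group's core when detected in
    more than ``prevalence`` of that group's samples.  The returned
    ``core_shared`` flag asserts the property that every group's core is
    contained in all groups' detected sets.
    """
    groups = groups.loc[table.sample_ids]
    names = sorted(groups.unique())
    if len(names) != 3:
        raise ValueError("core_shared_unique expects exactly three groups")
    detected = {}
    core = {}
    for g in names:
        cols = groups[groups == g].index
        sub = table.counts[cols]
        frac = (sub >= 1).mean(axis=1)
        detected[g] = set(frac[frac > 0].index)
        core[g] = set(frac[frac > prevalence].index)
    a, b, c = (detected[g] for g in names)
    venn = {
        "100": len(a - b - c),
        "010": len(b - a - c),
        "001": len(c - a - b),
        "110": len((a & b) - c),
        "101": len((a & c) - b),
        "011": len((b & c) - a),
        "111": len(a & b & c),
    }
    shared_all = a & b & c
    core_shared = all(core[g] <= shared_all for g in names)
    return {
        "group_order": names,
        "venn": venn,
        "detected": detected,
        "core": core,
        "core_shared": core_shared,
    }
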