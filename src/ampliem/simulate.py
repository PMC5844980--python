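"""Synthetic study generator: reference OTUs, error-bearing amplicon
reads, cohort metadata and nutrient tables with known ground truth.

The generator emulates a three-group dietary cohort (omnivore O,
vegetarian V, vegan VG; 43/32/26 subjects) profiled by V3-V4 16S
amplicon sequencing with two technical replicates per subject and
log-normal library sizes (mean ~11,000 reads, clipped to
[1,500, 30,000]).  Reads carry random substitutions and
homopolymer-run +/-1 indels, with per-base Phred scores drawn around a
configurable mean with a linear 3' decay so the Q32/50-base window
filter has non-trivial pass/fail behaviour.  Planted effects with known
ground truth:

* per-group expected richness (V > O by default, mirroring the cohort
  effect the statistics layer must recover),
* a fold-change on Bacteroidetes-affiliated OTUs in the plant-based
  groups,
* a latent enterotype per subject boosting one marker family, and
* group-specific means for selected nutrients (animal protein,
  cholesterol, EPA, DHA high in omnivores only).

One global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence.spawn`` in a fixed order (references,
cohort, compositions, reads, counts), so stages are independently
reproducible and identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import QualityRead
from .taxonomy import ReferenceOtu

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# family -> (phylum, class, order); marker families first
_FAMILIES = {
    "Bacteroidaceae": ("Bacteroidetes", "Bacteroidia", "Bacteroidales"),
    "Prevotellaceae": ("Bacteroidetes", "Bacteroidia", "Bacteroidales"),
    "Porphyromonadaceae": ("Bacteroidetes", "Bacteroidia", "Bacteroidales"),
    "Ruminococcaceae": ("Firmicutes", "Clostridia", "Clostridiales"),
    "Lachnospiraceae": ("Firmicutes", "Clostridia", "Clostridiales"),
    "Veillonellaceae": ("Firmicutes", "Negativicutes", "Selenomonadales"),
    "Enterobacteriaceae": ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales"),
    "Bifidobacteriaceae": ("Actinobacteria", "Actinobacteria", "Bifidobacteriales"),
    "Verrucomicrobiaceae": ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales"),
}
_FAMILY_WEIGHTS = {
    "Bacteroidaceae": 0.20,
    "Prevotellaceae": 0.10,
    "Porphyromonadaceae": 0.08,
    "Ruminococcaceae": 0.22,
    "Lachnospiraceae": 0.20,
    "Veillonellaceae": 0.06,
    "Enterobacteriaceae": 0.05,
    "Bifidobacteriaceae": 0.05,
    "Verrucomicrobiaceae": 0.04,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    # references
    n_otus: int = 300
    min_separation: float = 0.06  # twice the 3% clustering radius
    near_pair_fraction: float = 0.0  # fraction placed at 0.03-0.06 distance
    fraction_truncated_lineage: float = 0.10
    sequence_length_range: tuple[int, int] = (400, 470)
    # cohort
    group_sizes: dict = field(
        default_factory=lambda: {"O": 43, "V": 32, "VG": 26}
    )
    replicates: int = 2
    # sequencing
    library_mean: float = 11000.0
    library_sigma_log: float = 0.55
    library_range: tuple[int, int] = (1500, 30000)
    substitution_rate: float = 0.005
    homopolymer_indel_rate: float = 0.01
    quality_mean: float = 38.0
    quality_3prime_drop: float = 6.0
    quality_sd: float = 2.0
    # planted community effects
    richness_mean: dict = field(
        default_factory=lambda: {"O": 147.0, "V": 183.0, "VG": 175.0}
    )
    richness_sd: float = 25.0
    bacteroidetes_fold: dict = field(
        default_factory=lambda: {"O": 1.0, "V": 1.6, "VG": 1.6}
    )
    planted_enterotypes: bool = True
    enterotype_boost: float = 3.0
    abundance_sigma_log: float = 1.2
    # nutrients
    planted_nutrient_effects: bool = True
    nutrient_noise_sigma_log: float = 0.25

    def __post_init__(self) -> None:
        for r in (
            self.substitution_rate,
            self.homopolymer_indel_rate,
            self.near_pair_fraction,
            self.fraction_truncated_lineage,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates and fractions must lie in [0, 1]")
        if self.n_otus < 1 or self.replicates < 1:
            raise ValueError("sizes must be positive")

    def seeds(self) -> dict[str, np.random.SeedSequence]:
        """Fixed-order fan-out of the global seed into stage seeds."""
        ss = np.random.SeedSequence(self.seed)
        names = ("references", "cohort", "compositions", "reads", "counts")
        return dict(zip(names, ss.spawn(len(names))))


@dataclass
class GroundTruth:
    """What the generator planted, for checking recovery downstream."""

    group: dict[str, str]  # subject -> diet group
    compositions: dict[str, dict[str, float]]  # subject -> otu -> proportion
    richness: dict[str, int]  # subject -> number of OTUs present
    enterotype: dict[str, str]  # subject -> boosted marker family
    marked_taxa: list[str]  # OTUs carrying the group fold-change
    read_sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for subject, comp in self.compositions.items():
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition of {subject} sums to {total}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "group": self.group,
                    "compositions": self.compositions,
                    "richness": self.richness,
                    "enterotype": self.enterotype,
                    "marked_taxa": self.marked_taxa,
                    "read_sources": self.read_sources,
                },
                fh,
            )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = np.array(list(seq))
    n_mut = max(1, rng.binomial(len(chars), rate))
    pos = rng.choice(len(chars), size=n_mut, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != chars[p]]
        chars[p] = choices[rng.integers(3)]
    return "".join(chars)


def generate_references(config: SimulationConfig) -> list[ReferenceOtu]:
    """Generate reference OTUs with lineages and controlled separation.

    Well-separated references are independent random sequences (pairwise
    distance far above ``min_separation``); a ``near_pair_fraction`` of
    references is derived from an earlier reference by mutating 3.5-5.5%
    of positions to stress the clustering radius.  A seeded, exact
    ``round(fraction * n)`` subset of lineages is truncated at family
    level (no genus).
    """
    if config.min_separation > 0.3:
        raise ValueError(
            "cannot guarantee pairwise separation above 0.3 for random "
            "sequences of this length"
        )
    rng = np.random.default_rng(config.seeds()["references"])
    n = config.n_otus
    n_near = int(round(config.near_pair_fraction * n)) if n > 1 else 0
    fam_names = list(_FAMILIES)
    fam_p = np.array([_FAMILY_WEIGHTS[f] for f in fam_names])
    fam_p = fam_p / fam_p.sum()
    lo, hi = config.sequence_length_range

    refs: list[ReferenceOtu] = []
    genus_counter: dict[str, int] = {}
    for i in range(n):
        fam = str(rng.choice(fam_names, p=fam_p))
        phylum, klass, order = _FAMILIES[fam]
        genus_counter[fam] = genus_counter.get(fam, 0) + 1
        # a few genera per family, so genus-level collapsing is non-trivial
        genus = f"{fam[:-4]}_g{1 + (genus_counter[fam] - 1) % 4}"
        lineage = ("Bacteria", phylum, klass, order, fam, genus)
        if i >= n - n_near and refs:
            parent = refs[int(rng.integers(len(refs)))]
            seq = _mutate(rng, parent.sequence, float(rng.uniform(0.035, 0.055)))
        else:
            seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        refs.append(ReferenceOtu(id=f"ref{i:04d}", sequence=seq, lineage=lineage))

    n_trunc = int(round(config.fraction_truncated_lineage * n))
    if n_trunc:
        trunc_idx = rng.choice(n, size=n_trunc, replace=False)
        for i in trunc_idx:
            r = refs[i]
            refs[i] = ReferenceOtu(r.id, r.sequence, r.lineage[:5])
    return refs


def _subject_ids(config: SimulationConfig) -> list[tuple[str, str]]:
    out = []
    for g, size in config.group_sizes.items():
        for i in range(size):
            out.append((f"{g}{i + 1:02d}", g))
    return out


_NAMED_NUTRIENTS = [
    "fat_g",
    "protein_g",
    "carbohydrate_g",
    "animal_proteins_g",
    "cholesterol_mg",
    "EPA_g",
    "DHA_g",
    "fiber_g",
]
N_NUTRIENTS = 76

# group multipliers for the planted nutrient effects (O = 1 baseline)
_NUTRIENT_EFFECTS = {
    "animal_proteins_g": {"O": 1.0, "V": 0.25, "VG": 0.02},
    "cholesterol_mg": {"O": 1.0, "V": 0.40, "VG": 0.05},
    "EPA_g": {"O": 1.0, "V": 0.15, "VG": 0.05},
    "DHA_g": {"O": 1.0, "V": 0.15, "VG": 0.05},
    "fiber_g": {"O": 1.0, "V": 1.40, "VG": 1.60},
}
# daily-gram means; macros get group-specific means directly
_MACRO_MEANS = {
    "fat_g": {"O": 90.0, "V": 90.0, "VG": 90.0},
    "protein_g": {"O": 75.0, "V": 62.0, "VG": 58.0},
    "carbohydrate_g": {"O": 240.0, "V": 275.0, "VG": 265.0},
}
_NAMED_BASE = {
    "animal_proteins_g": 45.0,
    "cholesterol_mg": 280.0,
    "EPA_g": 0.25,
    "DHA_g": 0.45,
    "fiber_g": 22.0,
}


def nutrient_names() -> list[str]:
    return _NAMED_NUTRIENTS + [
        f"nutrient_{i:02d}" for i in range(len(_NAMED_NUTRIENTS) + 1, N_NUTRIENTS + 1)
    ]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort metadata and the 76-nutrient daily-intake table.

    Anthropometrics are drawn from the same distributions in every group
    (no planted effect); nutrients get group-specific means for the
    planted subset when ``planted_nutrient_effects`` is on.
    """
    rng = np.random.default_rng(config.seeds()["cohort"])
    subjects = _subject_ids(config)
    n = len(subjects)
    groups = [g for _, g in subjects]
    meta = pd.DataFrame(
        {
            "group": groups,
            "gender": np.where(rng.random(n) < 0.683, "F", "M"),
            "age": np.clip(rng.normal(42.5, 13.0, n), 18, 80).round(1),
            "bmi": np.clip(rng.normal(23.8, 4.4, n), 16, 40).round(1),
            "bfm": np.clip(rng.normal(24.9, 8.7, n), 5, 50).round(1),
            "blm": np.clip(rng.normal(75.5, 8.7, n), 50, 95).round(1),
            "region": rng.choice([f"R{i}" for i in range(1, 8)], size=n),
        },
        index=pd.Index([s for s, _ in subjects], name="sample"),
    )

    names = nutrient_names()
    base = {}
    for nm in names:
        if nm in _MACRO_MEANS:
            continue
        base[nm] = _NAMED_BASE.get(nm, float(np.exp(rng.normal(2.0, 1.0))))
    cols = {}
    sigma = config.nutrient_noise_sigma_log
    for nm in names:
        mean = np.empty(n)
        for i, g in enumerate(groups):
            if nm in _MACRO_MEANS:
                m = _MACRO_MEANS[nm][g] if config.planted_nutrient_effects else _MACRO_MEANS[nm]["O"]
            else:
                mult = (
                    _NUTRIENT_EFFECTS.get(nm, {}).get(g, 1.0)
                    if config.planted_nutrient_effects
                    else 1.0
                )
                m = base[nm] * mult
            mean[i] = m
        cols[nm] = mean * np.exp(rng.normal(0.0, sigma, n) - sigma**2 / 2)
    nutrients = pd.DataFrame(cols, index=meta.index)
    return meta, nutrients


# enterotype mixing per group, normalised from the cohort's published
# marker-family distribution (Bacteroidaceae / Prevotellaceae /
# Ruminococcaceae down the rows)
_ENTEROTYPE_PROBS = {
    "O": np.array([21, 9, 13], dtype=float) / 43,
    "VG": np.array([11, 5, 11], dtype=float) / 27,
    "V": np.array([11, 5, 16], dtype=float) / 32,
}
_MARKER_FAMILIES = ("Bacteroidaceae", "Prevotellaceae", "Ruminococcaceae")


def simulate_compositions(
    refs: list[ReferenceOtu],
    metadata: pd.DataFrame,
    config: SimulationConfig,
) -> GroundTruth:
    """Per-subject true OTU proportions with the planted effects.

    Subject richness is drawn per group; OTU inclusion follows a
    power-law prevalence (early references form a shared core); included
    OTUs get log-normal abundances scaled by the Bacteroidetes
    fold-change of the subject's group and the boost of the subject's
    latent enterotype family.
    """
    rng = np.random.default_rng(config.seeds()["compositions"])
    n_otus = len(refs)
    otu_ids = [r.id for r in refs]
    prevalence = 1.0 / (np.arange(n_otus) + 5.0)
    family = [r.lineage[4] if len(r.lineage) > 4 else None for r in refs]
    phylum = [r.lineage[1] if len(r.lineage) > 1 else None for r in refs]
    marked = [otu_ids[i] for i in range(n_otus) if phylum[i] == "Bacteroidetes"]

    group = {}
    comps = {}
    richness = {}
    enterotype = {}
    for subject, row in metadata.iterrows():
        g = row["group"]
        group[subject] = g
        r_mean = config.richness_mean.get(g, 150.0)
        r = int(np.clip(round(rng.normal(r_mean, config.richness_sd)), 5, n_otus))
        richness[subject] = r
        chosen = rng.choice(n_otus, size=r, replace=False, p=prevalence / prevalence.sum())
        chosen.sort()
        abun = np.exp(rng.normal(0.0, config.abundance_sigma_log, size=r))
        fold = config.bacteroidetes_fold.get(g, 1.0)
        if config.planted_enterotypes:
            et = str(rng.choice(_MARKER_FAMILIES, p=_ENTEROTYPE_PROBS[g]))
        else:
            et = ""
        enterotype[subject] = et
        for k, i in enumerate(chosen):
            if phylum[i] == "Bacteroidetes":
                abun[k] *= fold
            if et and family[i] == et:
                abun[k] *= config.enterotype_boost
        abun /= abun.sum()
        comps[subject] = {otu_ids[i]: float(a) for i, a in zip(chosen, abun)}
    return GroundTruth(
        group=group,
        compositions=comps,
        richness=richness,
        enterotype=enterotype,
        marked_taxa=marked,
    )


def _library_sizes(rng, config: SimulationConfig, n: int) -> np.ndarray:
    mu = np.log(config.library_mean) - config.library_sigma_log**2 / 2
    raw = np.exp(rng.normal(mu, config.library_sigma_log, size=n))
    lo, hi = config.library_range
    return np.clip(np.round(raw), lo, hi).astype(int)


def simulate_counts(
    refs: list[ReferenceOtu],
    truth: GroundTruth,
    config: SimulationConfig,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Multinomial OTU count table straight from the true compositions.

    A fast surrogate for full read simulation when only table-level
    behaviour matters (diversity, statistics); columns are subjects, or
    subject_rep when ``per_replicate``.  Replicates of a subject share
    the same composition.
    """
    rng = np.random.default_rng(config.seeds()["counts"])
    otu_ids = [r.id for r in refs]
    idx = {o: i for i, o in enumerate(otu_ids)}
    cols = {}
    for subject in truth.compositions:
        p = np.zeros(len(otu_ids))
        for o, v in truth.compositions[subject].items():
            p[idx[o]] = v
        reps = range(1, config.replicates + 1) if per_replicate else [None]
        libs = _library_sizes(rng, config, len(list(reps)))
        for r, lib in zip(reps, libs):
            name = subject if r is None else f"{subject}_{r}"
            cols[name] = rng.multinomial(lib, p)
    return pd.DataFrame(cols, index=otu_ids)


def _find_runs(seq: str) -> list[tuple[int, int]]:
    """(start, length) of homopolymer runs of length >= 2."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 2:
            runs.append((i, j - i))
        i = j
    return runs


def _sequencing_errors(rng, seq: str, config: SimulationConfig) -> str:
    if config.substitution_rate > 0:
        n_sub = rng.binomial(len(seq), config.substitution_rate)
        if n_sub:
            chars = list(seq)
            for p in rng.choice(len(chars), size=n_sub, replace=False):
                choices = [b for b in "ACGT" if b != chars[p]]
                chars[p] = choices[rng.integers(3)]
            seq = "".join(chars)
    if config.homopolymer_indel_rate > 0:
        edits = []  # (pos, +1 insert / -1 delete)
        for start, length in _find_runs(seq):
            if rng.random() < config.homopolymer_indel_rate:
                edits.append((start, 1 if rng.random() < 0.5 else -1))
        for pos, kind in sorted(edits, reverse=True):
            if kind > 0:
                seq = seq[: pos + 1] + seq[pos] + seq[pos + 1 :]
            else:
                seq = seq[:pos] + seq[pos + 1 :]
    return seq


def _quality_string(rng, length: int, config: SimulationConfig) -> np.ndarray:
    pos = np.arange(length) / max(length - 1, 1)
    mean = config.quality_mean - config.quality_3prime_drop * pos
    q = np.round(rng.normal(mean, config.quality_sd))
    return np.clip(q, 2, 41).astype(int)


def simulate_reads(
    refs: list[ReferenceOtu],
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[str, list[QualityRead]]:
    """Pre-merged amplicon reads per sample-replicate.

    Returns a mapping ``"<subject>_<rep>" -> [QualityRead, ...]`` and
    records every read's source OTU in ``truth.read_sources``.  Replicate
    pairs of a subject are drawn from the same composition.  A clipped
    library size of zero yields an empty record set with a warning.
    """
    rng = np.random.default_rng(config.seeds()["reads"])
    seq_of = {r.id: r.sequence for r in refs}
    out: dict[str, list[QualityRead]] = {}
    for subject in truth.compositions:
        comp = truth.compositions[subject]
        otus = list(comp)
        probs = np.array([comp[o] for o in otus])
        for rep in range(1, config.replicates + 1):
            sample = f"{subject}_{rep}"
            lib = int(_library_sizes(rng, config, 1)[0])
            if lib == 0:
                log.warning("zero library size for %s", sample)
                out[sample] = []
                continue
            counts = rng.multinomial(lib, probs)
            reads = []
            i = 0
            for o, c in zip(otus, counts):
                for _ in range(c):
                    rid = f"{sample}_r{i}"
                    i += 1
                    bases = _sequencing_errors(rng, seq_of[o], config)
                    reads.append(
                        QualityRead(
                            id=rid,
                            bases=bases,
                            quals=_quality_string(rng, len(bases), config),
                        )
                    )
                    truth.read_sources[rid] = o
            out[sample] = reads
    return out


def read_membership_accuracy(
    otus,
    truth: GroundTruth,
    reads_by_sample: dict[str, list[QualityRead]],
) -> float:
    """Fraction of clustered reads assigned to their true OTU.

    Each OTU is matched to the reference contributing most of its reads
    (majority vote); a read is correct when its own source equals its
    OTU's majority reference.  Reads removed by quality or abundance
    filtering never reach clustering and are not counted.
    """
    from .preprocess import normalize_sequence

    seq_to_otu: dict[str, str] = {}
    for o in otus.otus:
        for m in o.members:
            seq_to_otu[m.sequence] = o.id
    tallies: dict[str, dict[str, int]] = {}
    assignments: list[tuple[str, str]] = []  # (otu, true source) per read
    for reads in reads_by_sample.values():
        for r in reads:
            otu = seq_to_otu.get(normalize_sequence(r.bases))
            if otu is None:
                continue
            src = truth.read_sources[r.id]
            tallies.setdefault(otu, {})
            tallies[otu][src] = tallies[otu].get(src, 0) + 1
            assignments.append((otu, src))
    if not assignments:
        raise ValueError("no reads reached clustering")
    majority = {
        otu: max(sorted(c), key=lambda s: c[s]) for otu, c in tallies.items()
    }
    correct = sum(1 for otu, src in assignments if majority[otu] == src)
    return correct / len(assignments)


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    references: list[ReferenceOtu]
    metadata: pd.DataFrame
    nutrients: pd.DataFrame
    truth: GroundTruth


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """References + cohort + true compositions in one bundle (no reads)."""
    config = config or SimulationConfig()
    refs = generate_references(config)
    meta, nutrients = simulate_cohort(config)
    truth = simulate_compositions(refs, meta, config)
    return SimulatedStudy(config, refs, meta, nutrients, truth)
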