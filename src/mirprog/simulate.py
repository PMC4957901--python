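"""Synthetic miRNA/mRNA time-course data with planted ground truth.

Emulates the study design the pipeline is built for: four time points
(weeks 6-12 of tumor progression), tumor and control arms with a few
replicates each, miRNAs acting as tumor promoters (up in tumor, effect
growing over time) or suppressors (down, shrinking), target genes whose
tumor-arm mean is inversely coupled to their regulator's effect, decoy
miRNA-gene pairs that are statistically independent, and gene-term
annotation sets containing planted bicliques.  Counts follow a negative
binomial with a shared dispersion, and per-sample library-size factors
are log-normal so normalization is non-trivial.

Every quantity downstream stages infer (directions, negative
correlations, modules, regulators) is recorded in a ``GroundTruth`` so
recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import CountMatrix, TIMEPOINTS


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the design the pipeline targets: 4 time points x
    (3 tumor + 3 normal) replicates = 24 samples, a two-fold-per-stage
    effect (``effect_logfc`` is the log2 tumor/normal effect reached at
    the last time point; earlier points ramp up linearly, so promoter
    profiles are monotone non-decreasing and suppressors non-increasing),
    and a modest negative-binomial dispersion.
    """

    n_mirna: int = 80
    n_gene: int = 600
    n_timepoints: int = 4
    n_reps_per_arm: int = 3
    n_promoters: int = 10
    n_suppressors: int = 10
    targets_per_mirna: int = 10
    n_decoy_interactions: int = 100
    n_modules: int = 3
    module_gene_range: tuple[int, int] = (8, 12)
    module_term_range: tuple[int, int] = (2, 4)
    module_regulator_range: tuple[int, int] = (4, 8)
    n_background_terms: int = 40
    annotation_noise_rate: float = 0.02
    effect_logfc: float = 2.0
    dispersion: float = 0.02
    baseline_logmean_range: tuple[float, float] = (3.0, 11.0)
    libsize_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_promoters + self.n_suppressors > self.n_mirna:
            raise ValueError("more planted regulators than miRNAs")
        n_regs = self.n_promoters + self.n_suppressors
        if n_regs * self.targets_per_mirna > self.n_gene:
            raise ValueError("not enough genes for disjoint target sets")
        for name in ("n_mirna", "n_gene", "n_timepoints", "n_reps_per_arm",
                     "targets_per_mirna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.annotation_noise_rate < 0 or self.annotation_noise_rate >= 1:
            raise ValueError("annotation_noise_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    promoter_ids: set = field(default_factory=set)
    suppressor_ids: set = field(default_factory=set)
    true_interactions: set = field(default_factory=set)   # (mirna, gene)
    decoy_interactions: set = field(default_factory=set)  # (mirna, gene)
    planted_modules: list = field(default_factory=list)   # (genes, terms, regulators)
    annotations: dict = field(default_factory=dict)       # term -> gene set

    def regulator_of(self) -> dict:
        """gene -> its unique planted regulator."""
        return {g: m for m, g in self.true_interactions}

    def to_json(self) -> str:
        payload = {
            "promoter_ids": sorted(self.promoter_ids),
            "suppressor_ids": sorted(self.suppressor_ids),
            "true_interactions": sorted(map(list, self.true_interactions)),
            "decoy_interactions": sorted(map(list, self.decoy_interactions)),
            "planted_modules": [
                {"genes": sorted(g), "terms": sorted(t), "regulators": sorted(r)}
                for g, t, r in self.planted_modules
            ],
            "annotations": {t: sorted(g) for t, g in sorted(self.annotations.items())},
        }
        return json.dumps(payload, indent=1)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _effect_profile(config: SimulationConfig) -> np.ndarray:
    """Per-time-point log2 effect ramp, reaching effect_logfc at the end."""
    t = np.arange(1, config.n_timepoints + 1)
    return config.effect_logfc * t / config.n_timepoints


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Draw miRNA and mRNA count matrices with planted regulation.

    Promoter miRNAs carry a +effect ramp in the tumor arm, suppressors the
    mirror; each true target gene's tumor mean is multiplied by
    2^(-regulator effect), so across all samples regulator and target are
    negatively correlated in expectation while decoy pairs stay
    independent.  Same config and seed reproduce bit-identical matrices.
    """
    rng = np.random.default_rng(config.seed)
    timepoints = list(TIMEPOINTS[: config.n_timepoints])
    if config.n_timepoints > len(TIMEPOINTS):
        timepoints = [f"w{6 + 2 * i}" for i in range(config.n_timepoints)]

    mirna_ids = [f"mir{i + 1:04d}" for i in range(config.n_mirna)]
    gene_ids = [f"gene{i + 1:04d}" for i in range(config.n_gene)]

    regulators = rng.choice(config.n_mirna, config.n_promoters + config.n_suppressors, replace=False)
    promoters = [mirna_ids[i] for i in regulators[: config.n_promoters]]
    suppressors = [mirna_ids[i] for i in regulators[config.n_promoters:]]

    target_pool = rng.choice(
        config.n_gene,
        (config.n_promoters + config.n_suppressors) * config.targets_per_mirna,
        replace=False,
    )
    truth = GroundTruth(promoter_ids=set(promoters), suppressor_ids=set(suppressors))
    gene_effect = {}  # gene -> signed log2 effect ramp (regulator's, to invert)
    mirna_effect = {}
    ramp = _effect_profile(config)
    for r, mid in enumerate(promoters + suppressors):
        sign = 1.0 if mid in truth.promoter_ids else -1.0
        mirna_effect[mid] = sign * ramp
        block = target_pool[r * config.targets_per_mirna:(r + 1) * config.targets_per_mirna]
        for gi in block:
            gid = gene_ids[gi]
            truth.true_interactions.add((mid, gid))
            gene_effect[gid] = -sign * ramp

    # decoys: pairs with a non-target gene, hence independent of the miRNA
    target_genes = set(g for _, g in truth.true_interactions)
    free_genes = [g for g in gene_ids if g not in target_genes]
    n_decoy = min(config.n_decoy_interactions, config.n_mirna * len(free_genes))
    seen = set()
    while len(seen) < n_decoy:
        m = mirna_ids[rng.integers(config.n_mirna)]
        g = free_genes[rng.integers(len(free_genes))]
        seen.add((m, g))
    truth.decoy_interactions = seen

    # sample layout: grouped by time point, tumor then normal
    sample_ids, meta_rows = [], []
    for tp in timepoints:
        for cond in ("tumor", "normal"):
            for rep in range(1, config.n_reps_per_arm + 1):
                sid = f"{tp}_{cond}_{rep}"
                sample_ids.append(sid)
                meta_rows.append({"sample": sid, "timepoint": tp, "condition": cond,
                                  "replicate": rep})
    samples = pd.DataFrame(meta_rows).set_index("sample")
    libsize_factor = rng.lognormal(mean=0.0, sigma=config.libsize_sigma, size=len(sample_ids))

    lo, hi = config.baseline_logmean_range

    is_tumor = (samples["condition"] == "tumor").to_numpy()
    t_index = np.array([timepoints.index(tp) for tp in samples["timepoint"]])

    def _draw_matrix(ids, effects, length_range):
        # planted features get mid-range baselines so their fold-changes
        # stay inside the null features' range and survive rank-based
        # normalization; null features span the full range
        span = hi - lo
        logbase = rng.uniform(lo, hi, size=len(ids))
        planted = np.array([fid in effects for fid in ids])
        logbase[planted] = rng.uniform(
            lo + 0.4 * span, hi - 0.25 * span, size=int(planted.sum())
        )
        base = 2.0**logbase
        mean = np.tile(base[:, None], (1, len(sample_ids)))
        for fi, fid in enumerate(ids):
            eff = effects.get(fid)
            if eff is None:
                continue
            mean[fi, is_tumor] = base[fi] * 2.0 ** eff[t_index[is_tumor]]
        mean = mean * libsize_factor[None, :]
        counts = _nb_draw(rng, mean, config.dispersion)
        values = pd.DataFrame(counts, index=ids, columns=sample_ids)
        lengths = pd.Series(rng.integers(*length_range, size=len(ids)), index=ids)
        return CountMatrix(values=values, samples=samples.copy(), feature_lengths=lengths)

    mirna_counts = _draw_matrix(mirna_ids, mirna_effect, (18, 26))
    mrna_counts = _draw_matrix(gene_ids, gene_effect, (500, 5000))

    # planted gene-term modules over targets of disjoint regulator groups
    all_regs = promoters + suppressors
    reg_targets = {m: [g for mm, g in truth.true_interactions if mm == m] for m in all_regs}
    available_regs = list(all_regs)
    term_counter = 0
    for _ in range(config.n_modules):
        n_reg = int(rng.integers(config.module_regulator_range[0],
                                 config.module_regulator_range[1] + 1))
        n_reg = min(n_reg, len(available_regs))
        if n_reg == 0:
            break
        pick = rng.choice(len(available_regs), n_reg, replace=False)
        regs = [available_regs[i] for i in sorted(pick)]
        for m in regs:
            available_regs.remove(m)
        pool = sorted({g for m in regs for g in reg_targets[m]})
        n_genes = int(rng.integers(config.module_gene_range[0],
                                   config.module_gene_range[1] + 1))
        n_genes = min(n_genes, len(pool))
        # every chosen regulator must contribute at least one module gene
        chosen = {sorted(reg_targets[m])[int(rng.integers(len(reg_targets[m])))] for m in regs}
        rest = [g for g in pool if g not in chosen]
        extra = max(0, n_genes - len(chosen))
        if extra and rest:
            chosen |= set(np.array(rest)[rng.choice(len(rest), min(extra, len(rest)), replace=False)])
        n_terms = int(rng.integers(config.module_term_range[0],
                                   config.module_term_range[1] + 1))
        terms = set()
        for _ in range(n_terms):
            term_counter += 1
            terms.add(f"term{term_counter:03d}")
        regs_used = {m for m in regs if set(reg_targets[m]) & chosen}
        truth.planted_modules.append((frozenset(chosen), frozenset(terms), frozenset(regs_used)))
    return mirna_counts, mrna_counts, truth


def simulate_interaction_db(truth: GroundTruth) -> pd.DataFrame:
    """Candidate interaction table: union of true and decoy pairs.

    Each row carries a placeholder prediction score; duplicates collapse
    to a single row.
    """
    pairs = sorted(truth.true_interactions | truth.decoy_interactions)
    return pd.DataFrame(
        {"mirna": [m for m, _ in pairs],
         "gene": [g for _, g in pairs],
         "score": 1.0}
    )


def simulate_annotations(
    truth: GroundTruth,
    config: SimulationConfig,
    noise_rate: float | None = None,
) -> dict:
    """Gene-term annotation sets with planted bicliques and noise.

    Every planted module gene is annotated with every module term (a true
    biclique).  Background terms plus extra annotations are sprinkled at
    ``noise_rate`` per free gene x term cell.  The result (term -> gene
    set) is stored on ``truth.annotations`` and is GMT-serializable.
    """
    if noise_rate is None:
        noise_rate = config.annotation_noise_rate
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = [f"gene{i + 1:04d}" for i in range(config.n_gene)]
    annotations: dict[str, set] = {}
    for genes, terms, _ in truth.planted_modules:
        for t in terms:
            annotations.setdefault(t, set()).update(genes)
    for b in range(config.n_background_terms):
        annotations.setdefault(f"bgterm{b + 1:03d}", set())
    if noise_rate > 0:
        for t in sorted(annotations):
            planted = set(annotations[t])
            free = [g for g in gene_ids if g not in planted]
            hits = rng.random(len(free)) < noise_rate
            annotations[t].update(g for g, h in zip(free, hits) if h)
    annotations = {t: g for t, g in annotations.items() if g}
    truth.annotations = annotations
    return annotations
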