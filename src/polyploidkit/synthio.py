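"""Synthetic tetraploid data with known ground truth.

Emulates the structures the downstream analyses consume, at desk scale:

* a tetraploid genome of ``n_quartets`` homoeologous chromosome quartets
  (4 copies each, 48 chromosomes at the default 12), with per-copy gene
  retention (fractionation), shared family labels within a quartet, and
  tandem arrays emitted as consecutive same-family genes;
* aligned LTR pairs diverged at two configurable per-site differences —
  a larger between-subgenome difference (progenitor split) and a smaller
  within-subgenome one (polyploid event) — mutated site-by-site under a
  Jukes-Cantor process so the downstream correction is exact in
  expectation;
* negative-binomial expression counts over 14 libraries (3 fruit) with a
  configurable dominant chromosome copy per quartet whose identity can
  switch in fruit libraries;
* ORAC plates whose net AUC is exactly linear in Trolox-equivalent
  concentration plus optional Gaussian noise.

Randomness: one global seed feeds ``numpy.random.SeedSequence`` children
with fixed spawn keys per component (0 genome, 1 LTR, 2 counts, 3 plate),
so each ``simulate_*`` call is reproducible in isolation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import CYCLES, PlateRun, Well
from .errors import ConfigurationError
from .model import AlignedPair, Chromosome, ExpressionMatrix, Gene, GenomeLayout, Library

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_genome",
           "simulate_ltr_pairs", "simulate_counts", "simulate_plate",
           "default_libraries"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
FAMILY_LOGNORMAL_SIGMA = 0.5  # spread of per-family baseline expression
_COMPONENT_KEYS = {"genome": 0, "ltr": 1, "counts": 2, "plate": 3, "dominance": 4}


def default_libraries() -> list[Library]:
    """The 14-library panel: fruit developmental stages plus vegetative and
    stress tissues; libraries 4-6 (green, pink, ripe fruit) carry fruit=True."""
    tissues = ["flower_bud", "flower_anthesis", "petal_fall",
               "green_fruit", "pink_fruit", "ripe_fruit",
               "leaf_day", "leaf_night",
               "meja_leaf_1h", "meja_leaf_8h", "meja_leaf_24h",
               "shoot", "root", "salt_root"]
    fruit = {"green_fruit", "pink_fruit", "ripe_fruit"}
    return [Library(library_id=f"L{i + 1:02d}", tissue=t, fruit=t in fruit)
            for i, t in enumerate(tissues)]


@dataclass
class SimulationConfig:
    n_quartets: int = 12
    genes_per_chrom: int = 200
    quartet_retention_prob: float = 0.9
    tandem_rate: float = 0.05  # probability a retained gene seeds an array
    dominance_factor: float = 2.0
    dominant_copy_map: dict[int, int] | None = None  # quartet -> copy 1..4
    fruit_switch_prob: float = 0.8
    libraries: list[Library] = field(default_factory=default_libraries)
    nb_mean: float = 50.0
    nb_dispersion: float = 0.2  # var = m + disp * m^2
    size_factor_sigma: float = 0.25
    ltr_n_pairs: int = 200
    ltr_length_bp: int = 2000
    d_subgenome: float = 0.025
    d_haplotype: float = 0.0085
    seed: int = 0

    def __post_init__(self):
        for name in ("quartet_retention_prob", "tandem_rate", "fruit_switch_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in ("n_quartets", "genes_per_chrom", "ltr_n_pairs"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.ltr_length_bp < 100:
            raise ConfigurationError("ltr_length_bp must be >= 100")
        if not (self.d_subgenome > self.d_haplotype > 0):
            raise ConfigurationError(
                "require d_subgenome > d_haplotype > 0, got "
                f"{self.d_subgenome} and {self.d_haplotype}")
        if self.nb_mean < 0 or self.nb_dispersion < 0:
            raise ConfigurationError("nb_mean and nb_dispersion must be nonnegative")
        if self.dominance_factor <= 0:
            raise ConfigurationError("dominance_factor must be positive")
        if self.dominant_copy_map is not None:
            for q, c in self.dominant_copy_map.items():
                if not (1 <= c <= 4):
                    raise ConfigurationError(f"dominant copy for quartet {q} not in 1..4")

    def rng(self, component: str) -> np.random.Generator:
        """Component RNG from the global seed via a fixed spawn key."""
        key = _COMPONENT_KEYS[component]
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic data."""

    dominant_copy: dict[int, dict[str, int]] = field(default_factory=dict)
    tandem_members: dict[str, list[str]] = field(default_factory=dict)  # array id -> genes
    gene_family: dict[str, str] = field(default_factory=dict)
    ltr_true_d: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dominant_copy": {str(q): v for q, v in self.dominant_copy.items()},
            "tandem_members": self.tandem_members,
            "gene_family": self.gene_family,
            "ltr_true_d": self.ltr_true_d,
        }


def _chrom_id(quartet: int, copy: int, n_quartets: int) -> str:
    # copies of quartet q sit at chromosome numbers q, q+n, q+2n, q+3n,
    # mirroring a 12/24/36/48 homoeologous numbering
    return f"chr{quartet + n_quartets * (copy - 1):02d}"


def simulate_genome(config: SimulationConfig) -> tuple[GenomeLayout, SyntheticTruth]:
    """Generate the tetraploid gene layout and its ground truth.

    Each quartet has ``genes_per_chrom`` ancestral gene slots; each of its
    four chromosome copies retains a slot with ``quartet_retention_prob``.
    A retained gene seeds a tandem array with ``tandem_rate``; array sizes
    follow a geometric distribution truncated to [2, 10] and members are
    emitted consecutively. Deterministic for a fixed seed.
    """
    rng = config.rng("genome")
    truth = SyntheticTruth()
    chromosomes: list[Chromosome] = []
    genes: list[Gene] = []
    dominant_rng = config.rng("dominance")  # truth draws isolated from layout noise

    for q in range(1, config.n_quartets + 1):
        base = int(dominant_rng.integers(1, 5)) if config.dominant_copy_map is None \
            else config.dominant_copy_map.get(q, 1)
        if dominant_rng.random() < config.fruit_switch_prob:
            others = [c for c in (1, 2, 3, 4) if c != base]
            fruit = int(dominant_rng.choice(others))
        else:
            fruit = base
        truth.dominant_copy[q] = {"default": base, "fruit": fruit}

        families = [f"Q{q:02d}F{s:04d}" for s in range(1, config.genes_per_chrom + 1)]
        # homoeologous copies of a gene share their length (near-identical
        # sequences); lengths are drawn once per ancestral slot
        family_length = {fam: int(rng.integers(600, 3001)) for fam in families}
        for copy in (1, 2, 3, 4):
            chrom_id = _chrom_id(q, copy, config.n_quartets)
            retained = rng.random(config.genes_per_chrom) < config.quartet_retention_prob
            pos = 1
            rank = 0
            chrom_genes: list[Gene] = []
            for slot, family in enumerate(families):
                if not retained[slot]:
                    continue
                n_copies = 1
                if rng.random() < config.tandem_rate:
                    # geometric truncated to [2, 10]
                    size = 2 + int(rng.geometric(0.5)) - 1
                    n_copies = min(size, 10)
                array_ids = []
                for _ in range(n_copies):
                    rank += 1
                    length = family_length[family]
                    gap = int(rng.integers(200, 2001))
                    start = pos + gap
                    end = start + length - 1
                    gene_id = f"{chrom_id}g{rank:04d}"
                    strand = "+" if rng.random() < 0.5 else "-"
                    chrom_genes.append(Gene(gene_id, chrom_id, start, end,
                                            strand, family, rank))
                    truth.gene_family[gene_id] = family
                    array_ids.append(gene_id)
                    pos = end
                if n_copies >= 2:
                    truth.tandem_members[f"{chrom_id}:{family}"] = array_ids
            chrom_len = pos + 500
            chromosomes.append(Chromosome(chrom_id, q, copy, chrom_len))
            genes.extend(chrom_genes)
    return GenomeLayout(chromosomes=chromosomes, genes=genes), truth


def simulate_ltr_pairs(config: SimulationConfig,
                       truth: SyntheticTruth | None = None) -> list[AlignedPair]:
    """Aligned LTR pairs at the configured per-site differences.

    ``ltr_n_pairs`` pairs are generated per class: 'subgenome' pairs at
    ``d_subgenome`` and 'haplotype' pairs at ``d_haplotype``. One sequence
    of each pair is mutated site-by-site with substitution probability
    equal to the target difference, each substitution uniform over the
    three alternative bases (Jukes-Cantor process), so the measured d is
    unbiased for the target.
    """
    rng = config.rng("ltr")
    pairs: list[AlignedPair] = []
    for cls, d_target in (("subgenome", config.d_subgenome),
                          ("haplotype", config.d_haplotype)):
        for i in range(config.ltr_n_pairs):
            anc = rng.integers(0, 4, size=config.ltr_length_bp)
            mutate = rng.random(config.ltr_length_bp) < d_target
            shift = rng.integers(1, 4, size=config.ltr_length_bp)
            derived = np.where(mutate, (anc + shift) % 4, anc)
            seq_a = _BASES[anc].tobytes().decode()
            seq_b = _BASES[derived].tobytes().decode()
            label = f"{cls}_{i:04d}"
            pairs.append(AlignedPair(seq_a=seq_a, seq_b=seq_b, label=label))
            if truth is not None:
                truth.ltr_true_d[label] = d_target
    return pairs


def simulate_counts(layout: GenomeLayout, truth: SyntheticTruth,
                    config: SimulationConfig) -> ExpressionMatrix:
    """Negative-binomial read counts for every gene across the libraries.

    Mean[g, l] = family baseline (log-normal around ``nb_mean``) x library
    size factor (log-normal, sigma ``size_factor_sigma``) x
    ``dominance_factor`` when g sits on the dominant copy of its quartet
    for l's tissue class (fruit libraries use the fruit-switched copy).
    Variance is m + nb_dispersion * m^2.
    """
    rng = config.rng("counts")
    libs = config.libraries
    chrom_info = {c.chrom_id: c for c in layout.chromosomes}
    size_f = np.exp(rng.normal(0.0, config.size_factor_sigma, size=len(libs)))

    family_baseline: dict[str, float] = {}
    for fam in sorted({g.family for g in layout.genes}):
        family_baseline[fam] = config.nb_mean * float(
            np.exp(rng.normal(0.0, FAMILY_LOGNORMAL_SIGMA)))

    genes = layout.genes
    n_g, n_l = len(genes), len(libs)
    means = np.zeros((n_g, n_l))
    for gi, g in enumerate(genes):
        c = chrom_info[g.chrom_id]
        dom = truth.dominant_copy.get(c.quartet_id, {"default": 0, "fruit": 0})
        base = family_baseline[g.family]
        for li, lib in enumerate(libs):
            dominant = dom["fruit"] if lib.fruit else dom["default"]
            boost = config.dominance_factor if c.copy_index == dominant else 1.0
            means[gi, li] = base * size_f[li] * boost

    if config.nb_dispersion > 0:
        n_param = 1.0 / config.nb_dispersion
        with np.errstate(divide="ignore", invalid="ignore"):
            p = n_param / (n_param + means)
        counts = np.where(means > 0,
                          rng.negative_binomial(n_param, np.clip(p, 1e-12, 1.0)),
                          0)
    else:
        counts = rng.poisson(means)
    df = pd.DataFrame(counts.astype(np.int64),
                      index=[g.gene_id for g in genes],
                      columns=[l.library_id for l in libs])
    lengths = pd.Series({g.gene_id: g.end - g.start + 1 for g in genes})
    return ExpressionMatrix(counts=df, gene_length_bp=lengths, libraries=list(libs))


# ---------------------------------------------------------------------------
# Plate simulation

_FAST_TAU = 2.0
_SLOW_TAU = 30.0
_GAIN = 50_000.0


def _shapes(n_cycles: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(n_cycles)
    return np.exp(-i / _FAST_TAU), np.exp(-i / _SLOW_TAU)


def simulate_plate(n_standards: int = 4, n_samples: int = 6,
                   noise_sd: float = 0.0, n_replicates: int = 2,
                   sample_te_uM=None, dilution: float = 80.0,
                   mass_mg: float = 25.0, seed: int = 0,
                   n_cycles: int = CYCLES) -> tuple[PlateRun, dict]:
    """Simulate an ORAC plate (70 cycles at 90 s) with known Trolox truths.

    Decay curves are convex mixtures of a fast and a slow exponential
    chosen so the trapezoidal net AUC is exactly linear in the
    Trolox-equivalent concentration; Gaussian noise of SD ``noise_sd``
    (AUC units) is added to each well's target AUC. Standards span the
    12.5-100 uM calibration range. Returns (PlateRun, truth) where truth
    holds per-sample TE concentrations and the generative line.
    """
    if n_standards < 2:
        raise ConfigurationError("need >= 2 standard concentrations")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    fast, slow = _shapes(n_cycles)
    auc_fast = float(np.trapezoid(fast))
    auc_slow = float(np.trapezoid(slow))
    slope = 0.8 * (auc_slow - auc_fast) / 150.0  # net AUC per uM, keeps mixtures valid
    concs = np.geomspace(12.5, 100.0, n_standards)

    if sample_te_uM is None:
        sample_te_uM = rng.uniform(20.0, 80.0, size=n_samples)
    sample_te_uM = np.asarray(sample_te_uM, dtype=float)

    def make_series(te: float) -> np.ndarray:
        target = auc_fast + slope * te + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        lam = (target - auc_fast) / (auc_slow - auc_fast)
        series = (1.0 - lam) * fast + lam * slow
        return _GAIN * np.maximum(series, 0.0)

    wells = [Well(well_id=f"B{b + 1:02d}", role="blank",
                  fluorescence=make_series(0.0)) for b in range(2)]
    for si, c in enumerate(concs):
        for r in range(n_replicates):
            wells.append(Well(well_id=f"S{si + 1:02d}r{r + 1}", role="standard",
                              concentration_uM=float(c),
                              fluorescence=make_series(float(c))))
    for k, te in enumerate(sample_te_uM):
        for r in range(n_replicates):
            wells.append(Well(well_id=f"X{k + 1:02d}r{r + 1}", role="sample",
                              sample_id=f"sample{k + 1:02d}",
                              dilution=dilution, mass_mg=mass_mg,
                              fluorescence=make_series(float(te))))
    truth = {
        "te_uM": {f"sample{k + 1:02d}": float(te) for k, te in enumerate(sample_te_uM)},
        "slope_auc_per_uM": slope,
        "blank_auc": auc_fast,
        "dilution": dilution,
        "mass_mg": mass_mg,
    }
    return PlateRun(wells=wells), truth
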