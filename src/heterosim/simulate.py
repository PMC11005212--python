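"""Synthetic phenotype tables and hybrid-parent trio count matrices.

The generators produce data with *known ground truth* — a per-line tolerance
effect for the phenotype table, a per-gene expression class for the trio
counts — so every downstream stage (tolerance scoring, differential
expression, profile classification, enrichment) can be verified end to end
without the study's raw measurements.

Phenotype model
    Each F1 line (and each parent) carries a single waterlogging-tolerance
    multiplier ``w``: treatment replicate values are ``baseline * w * noise``
    and control replicates ``baseline * noise``, with multiplicative
    log-normal noise of a configured coefficient of variation.  The
    tolerance index (treatment mean / control mean) therefore recovers ``w``
    exactly in the noise-free limit.

Count model
    Per-gene group means for the maternal parent, paternal parent and hybrid
    are set by the gene's true class (one of the eight profiles or a null
    class); replicate counts are negative-binomial with mean ``mu * f_s``
    (``f_s`` a per-sample library-size factor) and variance
    ``mu + dispersion * mu**2``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhenoSimConfig",
    "TrioSimConfig",
    "ConfigError",
    "DEFAULT_TRAITS",
    "PROFILES",
    "CLASSES",
    "simulate_phenotypes",
    "simulate_trio_counts",
    "simulate_annotation",
    "class_group_means",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


#: the seven phenotyped traits: a morphological stress score (treatment only)
#: plus six growth/biomass traits measured under both conditions
DEFAULT_TRAITS = ("Score", "SH", "RL", "SFW", "RFW", "SDW", "RDW")

#: control-condition baseline per trait (trait-specific units: points, cm, g)
DEFAULT_BASELINES = {
    "Score": 20.0,
    "SH": 30.0,
    "RL": 10.0,
    "SFW": 10.0,
    "RFW": 4.0,
    "SDW": 1.5,
    "RDW": 0.4,
}

#: traits measured only under treatment (no control, hence no tolerance index)
TREATMENT_ONLY_TRAITS = frozenset({"Score"})

PROFILES = ("P0", "P1", "P2", "P3", "P4", "P5", "P6", "P7")
CLASSES = PROFILES + ("null",)


@dataclass(frozen=True)
class PhenoSimConfig:
    """Settings for the F1 population phenotype generator.

    Defaults mirror the study design: 140 F1 lines plus two parents, seven
    traits, 10 treatment and 6 control replicates per entry.  The maternal
    parent is waterlogging tolerant, the paternal parent sensitive.
    """

    n_lines: int = 140
    traits: tuple = DEFAULT_TRAITS
    reps_control: int = 6
    reps_treatment: int = 10
    parent_tolerance: tuple = (0.65, 0.25)  # (maternal, paternal) multipliers
    line_tolerance_mean: float = 0.46
    line_tolerance_sd: float = 0.15
    noise_cv: float = 0.15
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    maternal_id: str = "maternal"
    paternal_id: str = "paternal"
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 1:
            raise ConfigError("n_lines must be >= 1")
        if self.reps_control < 2 or self.reps_treatment < 2:
            raise ConfigError("replicate counts must be >= 2")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.line_tolerance_sd < 0:
            raise ConfigError("line_tolerance_sd must be >= 0")
        if any(t not in self.baselines for t in self.traits):
            raise ConfigError("every trait needs a baseline")
        if any(self.baselines[t] <= 0 for t in self.traits):
            raise ConfigError("trait baselines must be > 0")
        if len(self.parent_tolerance) != 2 or any(
            w <= 0 for w in self.parent_tolerance
        ):
            raise ConfigError("parent_tolerance must be two positive multipliers")


def _default_class_proportions() -> dict:
    # null majority: median-of-ratios normalization (like real RNA-seq data)
    # assumes most genes are not differential between any two samples
    props = {p: 0.05 for p in PROFILES}
    props["null"] = 0.6
    return props


@dataclass(frozen=True)
class TrioSimConfig:
    """Settings for the trio (maternal/paternal/hybrid) count generator."""

    n_genes: int = 5000
    reps_per_group: int = 3
    class_proportions: dict = field(default_factory=_default_class_proportions)
    effect_size: float = 4.0  # minimum fold separation between differing groups
    dispersion: float = 0.05  # NB dispersion phi: var = mu + phi * mu**2
    mean_log_range: tuple = (2.0, 3.5)  # log10 of baseline means
    conditions: tuple = ("control", "stress")
    library_factor_range: tuple = (0.7, 1.3)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.reps_per_group < 2:
            raise ConfigError("reps_per_group must be >= 2")
        if self.effect_size <= 1:
            raise ConfigError("effect_size must be > 1")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ConfigError(f"unknown classes in class_proportions: {unknown}")
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ConfigError(f"class_proportions must sum to 1 (got {total})")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ConfigError("class proportions must be >= 0")
        lo, hi = self.mean_log_range
        if not lo <= hi:
            raise ConfigError("mean_log_range must be (low, high)")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV (log-normal)."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def simulate_phenotypes(cfg: PhenoSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a replicated phenotype table for parents plus F1 lines.

    Returns
    -------
    table : DataFrame
        Long format with columns ``line_id, trait, condition, replicate,
        value``.  Treatment-only traits (Score) have no control rows.
    truth : DataFrame
        Per-entry true tolerance multiplier (columns ``line_id, tolerance``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    line_ids = [cfg.maternal_id, cfg.paternal_id] + [
        f"F{i + 1:03d}" for i in range(cfg.n_lines)
    ]
    tolerance = np.empty(len(line_ids))
    tolerance[0], tolerance[1] = cfg.parent_tolerance
    # truncated normal keeps tolerance positive; wide tails give the
    # transgressive segregation the population shows
    draws = rng.normal(cfg.line_tolerance_mean, cfg.line_tolerance_sd, cfg.n_lines)
    tolerance[2:] = np.clip(draws, 0.02, 1.5)

    records = []
    for line, w in zip(line_ids, tolerance):
        for trait in cfg.traits:
            base = cfg.baselines[trait]
            conditions = (
                ("treatment",)
                if trait in TREATMENT_ONLY_TRAITS
                else ("control", "treatment")
            )
            for cond in conditions:
                n = cfg.reps_treatment if cond == "treatment" else cfg.reps_control
                mean = base * w if cond == "treatment" else base
                values = mean * _lognormal_noise(rng, cfg.noise_cv, n)
                for r, v in enumerate(values, start=1):
                    records.append((line, trait, cond, r, v))

    table = pd.DataFrame(
        records, columns=["line_id", "trait", "condition", "replicate", "value"]
    )
    truth = pd.DataFrame({"line_id": line_ids, "tolerance": tolerance})
    return table, truth


def class_group_means(
    label: str, base: float, effect_size: float
) -> tuple[float, float, float]:
    """True (maternal, paternal, hybrid) means for one gene of a given class.

    Adjacent distinct levels are ``effect_size``-fold apart for the dominance,
    transgressive and null classes.  For the two additive classes the hybrid
    sits at the arithmetic mid-parent, which caps its fold separation from
    the high parent below 2 regardless of the parents; the parents are
    therefore spread ``effect_size**2``-fold so both hybrid-parent contrasts
    stay near that ceiling.
    """
    s = effect_size
    s2 = s * s
    if label == "null":
        return base, base, base
    if label == "P5":  # transgressive up
        return base, base, s * base
    if label == "P2":  # transgressive down
        return s * base, s * base, base
    if label == "P1":  # maternal dominance, maternal < paternal
        return base, s * base, base
    if label == "P6":  # maternal dominance, maternal > paternal
        return s * base, base, s * base
    if label == "P3":  # paternal dominance, paternal < maternal
        return s * base, base, base
    if label == "P4":  # paternal dominance, paternal > maternal
        return base, s * base, s * base
    if label == "P0":  # additive, maternal < paternal
        return base, s2 * base, (1 + s2) / 2.0 * base
    if label == "P7":  # additive, maternal > paternal
        return s2 * base, base, (1 + s2) / 2.0 * base
    raise ValueError(f"unknown class label {label!r}")


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu**2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_trio_counts(
    cfg: TrioSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x sample count matrix for a hybrid-parent trio.

    Returns
    -------
    counts : DataFrame
        Integer counts, genes as rows, samples as columns.
    samples : DataFrame
        Sample sheet with columns ``sample_id, role, condition, replicate,
        library_factor`` (role in maternal/paternal/hybrid).
    truth : DataFrame
        Per-gene true class (columns ``gene, label``) plus the true group
        means (``mu_maternal, mu_paternal, mu_hybrid``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]

    labels_pool = sorted(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[c] for c in labels_pool])
    probs = probs / probs.sum()
    labels = rng.choice(labels_pool, size=cfg.n_genes, p=probs)

    lo, hi = cfg.mean_log_range
    base = 10.0 ** rng.uniform(lo, hi, size=cfg.n_genes)

    mu = np.empty((cfg.n_genes, 3))  # columns: maternal, paternal, hybrid
    for i, (lab, b) in enumerate(zip(labels, base)):
        mu[i] = class_group_means(lab, b, cfg.effect_size)

    roles = ("maternal", "paternal", "hybrid")
    sample_rows = []
    col_means = []
    flo, fhi = cfg.library_factor_range
    for cond in cfg.conditions:
        for role_idx, role in enumerate(roles):
            for rep in range(1, cfg.reps_per_group + 1):
                f = rng.uniform(flo, fhi)
                sid = f"{role}_{cond}_r{rep}"
                sample_rows.append((sid, role, cond, rep, f))
                col_means.append(mu[:, role_idx] * f)

    mean_matrix = np.column_stack(col_means)
    counts = _nb_counts(rng, mean_matrix, cfg.dispersion)

    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "role", "condition", "replicate", "library_factor"],
    )
    counts_df = pd.DataFrame(counts, index=genes, columns=samples["sample_id"])
    counts_df.index.name = "gene"
    truth = pd.DataFrame(
        {
            "gene": genes,
            "label": labels,
            "mu_maternal": mu[:, 0],
            "mu_paternal": mu[:, 1],
            "mu_hybrid": mu[:, 2],
        }
    )
    return counts_df, samples, truth


def simulate_annotation(
    genes,
    n_terms: int = 50,
    term_size_range: tuple = (10, 200),
    enriched_in=None,
    n_enriched_terms: int = 0,
    enrichment_bias: float = 0.8,
    seed: int = 0,
) -> dict:
    """Random GMT-style annotation over the given gene universe.

    The first ``n_enriched_terms`` terms draw a fraction ``enrichment_bias``
    of their members from ``enriched_in``, giving terms that a correct
    over-representation test should rank first.

    Returns a mapping ``term_id -> (description, set of member genes)``.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    enriched_in = list(enriched_in) if enriched_in is not None else []
    lo, hi = term_size_range
    annotation = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(genes))
        if t < n_enriched_terms and enriched_in:
            k_bias = min(int(round(enrichment_bias * size)), len(enriched_in))
            biased = rng.choice(enriched_in, size=k_bias, replace=False)
            rest = rng.choice(genes, size=size - k_bias, replace=False)
            members = set(biased) | set(rest)
            desc = "synthetic enriched term"
        else:
            members = set(rng.choice(genes, size=size, replace=False))
            desc = "synthetic background term"
        annotation[f"TERM:{t + 1:04d}"] = (desc, members)
    return annotation


def config_to_dict(cfg) -> dict:
    """Flatten a simulation config dataclass for YAML serialization."""
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
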