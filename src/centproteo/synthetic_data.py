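"""Cohort and expression-matrix simulator with a planted-truth ledger.

Generates serum aptamer-proteomics data with the structure the analysis
assumes: three groups (centenarians, centenarians' offspring, unrelated
age-matched controls), log-normal relative-fluorescence-unit (RFU)
abundances, planted centenarian fold changes, additive sex and
collection-year covariate shifts, coherent correlated-protein modules
driven by Gaussian latent factors, a latent survival class with a
log-scale shift on designated proteins, and Gaussian log-scale noise.

The default configuration reproduces the cohort shape of the study this
package models: 77 centenarians (mean age 105.7, SD 3.6, 66% female),
82 offspring (71.2, 9.3, 66% female), 65 controls (70.6, 7.8, 55%
female), a 4785-aptamer platform with roughly 15% of aptamers raised in
centenarians (fold changes 1.02-3.33, median ~1.26) and 15% lowered
(0.56-0.97, median ~0.88).

Every artifact is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthLedger",
    "simulate_cohort",
    "simulate_external_study",
    "make_fixture_gene_sets",
]

GROUPS = ("centenarian", "offspring", "control")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort simulator; defaults emulate the modeled study."""

    n_centenarians: int = 77
    n_offspring: int = 82
    n_controls: int = 65
    female_fraction_per_group: tuple = (0.66, 0.66, 0.55)
    #: (mean, sd) of age at blood draw per group, years
    age_mean_sd_per_group: tuple = ((105.7, 3.6), (71.2, 9.3), (70.6, 7.8))
    n_aptamers: int = 4785
    #: fraction of aptamers planted higher / lower in centenarians
    frac_up: float = 733 / 4785
    frac_down: float = 695 / 4785
    fc_up_range: tuple = (1.02, 3.33)
    fc_down_range: tuple = (0.56, 0.97)
    #: target median planted fold change within each range
    fc_up_median: float = 1.26
    fc_down_median: float = 0.88
    residual_sd_log: float = 0.25
    sex_effect_sd: float = 0.05
    batch_effect_sd: float = 0.02
    collection_year_range: tuple = (2003, 2016)
    n_modules: int = 8
    module_size_range: tuple = (20, 480)
    module_latent_sd: float = 0.2
    n_survival_proteins: int = 40
    survival_effect_log: float = 0.3
    #: fraction of gene symbols shared by two aptamers (platform redundancy)
    duplicate_symbol_fraction: float = 0.14
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_centenarians, self.n_offspring, self.n_controls,
                  self.n_aptamers)
        if any(c <= 0 for c in counts):
            raise ValueError("all cohort/platform counts must be positive")
        for f in (*self.female_fraction_per_group, self.frac_up, self.frac_down):
            if not 0 <= f <= 1:
                raise ValueError(f"proportion out of [0,1]: {f}")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        lo, hi = self.fc_up_range
        if not (1 < lo <= hi):
            raise ValueError("fc_up_range must lie in (1, inf)")
        lo, hi = self.fc_down_range
        if not (0 < lo <= hi < 1):
            raise ValueError("fc_down_range must lie in (0, 1)")
        if self.n_modules > 0:
            if self.n_modules * self.module_size_range[0] > self.n_aptamers:
                raise ValueError(
                    "planted module sizes exceed the number of aptamers")


@dataclass
class TruthLedger:
    """Ground truth of one simulated dataset, for recovery scoring."""

    planted_direction: pd.Series  # per aptamer: up / down / null
    planted_fc: pd.Series         # centenarian vs younger, 1.0 for nulls
    module_assignment: pd.Series  # module id (M1..) or "unassigned"
    survival_effect: pd.Series    # signed log-RFU shift per survival class
    group_of_sample: pd.Series
    survival_class_of_sample: pd.Series  # short / long per sample

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "planted_direction": self.planted_direction,
            "planted_fc": self.planted_fc,
            "module_assignment": self.module_assignment,
            "survival_effect": self.survival_effect,
        })


def _truncated_exponential(rng, lo, hi, median, size):
    """Draws in [lo, hi] with approximate median ``median`` (lo<median<hi).

    A shifted exponential with rate ln2/(median-lo), resampled into the
    interval; skewed toward lo like observed fold-change spectra.
    """
    rate = np.log(2.0) / max(median - lo, 1e-9)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = lo + rng.exponential(1.0 / rate, size=2 * (size - filled) + 8)
        draw = draw[draw <= hi][: size - filled]
        out[filled : filled + len(draw)] = draw
        filled += len(draw)
    return out


def _aptamer_ids(n: int, rng: np.random.Generator) -> list[str]:
    base = rng.choice(np.arange(1000, 20000), size=n, replace=False)
    variant = rng.integers(1, 100, size=n)
    rev = rng.integers(1, 5, size=n)
    return [f"{b}-{v}_{r}" for b, v, r in zip(base, variant, rev)]


def _gene_symbols(n_aptamers: int, dup_fraction: float,
                  rng: np.random.Generator) -> list[str]:
    n_dup_pairs = int(round(dup_fraction * n_aptamers / 2))
    n_unique = n_aptamers - n_dup_pairs
    symbols = [f"G{idx:05d}" for idx in range(1, n_unique + 1)]
    dup_sources = rng.choice(n_unique, size=n_dup_pairs, replace=False)
    symbols += [symbols[i] for i in dup_sources]
    order = rng.permutation(n_aptamers)
    return [symbols[i] for i in order]


def simulate_cohort(config: SimulationConfig):
    """Simulate (expression, samples, aptamers, truth) for one cohort.

    Log-RFU of aptamer j in sample i is

        baseline_j + 1[group_i = centenarian] * log(planted_fc_j)
        + sex and collection-year shifts + module latent term
        + survival-class term + N(0, residual_sd_log^2)

    and the emitted matrix is exp() of that, hence strictly positive.
    Returns (expression DataFrame samples x aptamers, sample table,
    aptamer table, TruthLedger).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_per_group = (config.n_centenarians, config.n_offspring, config.n_controls)
    n_samples = sum(n_per_group)
    m = config.n_aptamers

    # --- samples ------------------------------------------------------
    groups = np.repeat(GROUPS, n_per_group)
    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    # exact female counts per group (rounded), order shuffled
    sex_parts = []
    for n, f in zip(n_per_group, config.female_fraction_per_group):
        n_f = int(round(f * n))
        part = np.array([1] * n_f + [0] * (n - n_f))  # 1 = female
        rng.shuffle(part)
        sex_parts.append(part)
    sex = np.concatenate(sex_parts)
    age = np.concatenate([
        rng.normal(mu, sd, size=n)
        for n, (mu, sd) in zip(n_per_group, config.age_mean_sd_per_group)
    ])
    y0, y1 = config.collection_year_range
    year = rng.integers(y0, y1 + 1, size=n_samples)

    # latent survival class: short/long straddling the group cutoffs.
    # Centenarians: ~42/31 short/long of 73 labeled; younger: ~22/48 of 70.
    surv_class = np.empty(n_samples, dtype=object)
    surv_years = np.full(n_samples, np.nan)
    dead = np.zeros(n_samples, dtype=bool)
    cent = groups == "centenarian"
    p_short_cent, p_short_young = 42 / 73, 22 / 70
    is_short = np.where(cent, rng.random(n_samples) < p_short_cent,
                        rng.random(n_samples) < p_short_young)
    surv_class[:] = np.where(is_short, "short", "long")
    # observed follow-up: class-conditional, straddling 2y (cent) / 10y cutoffs
    surv_years[cent & is_short] = rng.uniform(0.1, 1.9, (cent & is_short).sum())
    surv_years[cent & ~is_short] = rng.uniform(2.2, 8.0, (cent & ~is_short).sum())
    surv_years[~cent & is_short] = rng.uniform(1.0, 9.8, (~cent & is_short).sum())
    surv_years[~cent & ~is_short] = rng.uniform(10.5, 16.0, (~cent & ~is_short).sum())
    dead[cent] = True  # nearly all centenarians deceased at last contact
    # younger short-survivors are deaths; long survivors mostly alive
    dead[~cent & is_short] = True
    # a small fraction with insufficient follow-up (alive, short follow-up)
    insufficient = (~cent) & (~is_short) & (rng.random(n_samples) < 0.08)
    surv_years[insufficient] = rng.uniform(2.0, 9.0, insufficient.sum())
    surv_class[insufficient] = "unlabeled"

    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "group": groups,
        "sex": np.where(sex == 1, "F", "M"),
        "age_at_draw": np.round(age, 2),
        "collection_year": year,
        "survival_years": np.round(surv_years, 3),
        "dead": dead.astype(int),
    }).set_index("sample_id")

    # --- aptamers and planted truth ----------------------------------
    apt_ids = _aptamer_ids(m, rng)
    symbols = _gene_symbols(m, config.duplicate_symbol_fraction, rng)
    uniprot = [f"P{rng.integers(10000, 99999):05d}" for _ in range(m)]
    aptamers = pd.DataFrame({
        "aptamer_id": apt_ids,
        "uniprot": uniprot,
        "gene_symbol": symbols,
    }).set_index("aptamer_id")

    n_up = int(round(config.frac_up * m))
    n_down = int(round(config.frac_down * m))
    perm = rng.permutation(m)
    up_idx, down_idx = perm[:n_up], perm[n_up : n_up + n_down]
    direction = np.full(m, "null", dtype=object)
    direction[up_idx], direction[down_idx] = "up", "down"
    fc = np.ones(m)
    if n_up:
        fc[up_idx] = _truncated_exponential(
            rng, *config.fc_up_range, config.fc_up_median, n_up)
    if n_down:
        # mirror the up-draw in log space onto (0, 1)
        lo, hi = config.fc_down_range
        fc[down_idx] = 1.0 / _truncated_exponential(
            rng, 1.0 / hi, 1.0 / lo, 1.0 / config.fc_down_median, n_down)

    # modules: contiguous blocks over a fresh permutation, coherent loadings
    module_assignment = np.full(m, "unassigned", dtype=object)
    module_sizes = []
    if config.n_modules > 0:
        lo, hi = config.module_size_range
        hi_eff = min(hi, max(lo, m // max(config.n_modules, 1)))
        sizes = rng.integers(lo, hi_eff + 1, size=config.n_modules)
        order = rng.permutation(m)
        pos = 0
        for mi, size in enumerate(sizes, start=1):
            members = order[pos : pos + size]
            module_assignment[members] = f"M{mi}"
            module_sizes.append(int(size))
            pos += size

    surv_effect = np.zeros(m)
    n_surv = min(config.n_survival_proteins, m)
    surv_idx = rng.choice(m, size=n_surv, replace=False)
    surv_effect[surv_idx] = rng.choice([-1.0, 1.0], size=n_surv) * \
        config.survival_effect_log

    # --- expression ---------------------------------------------------
    baseline = rng.normal(7.0, 1.0, size=m)
    sex_coef = rng.normal(0.0, config.sex_effect_sd, size=m)
    year_coef = rng.normal(0.0, config.batch_effect_sd, size=m)
    log_rfu = np.tile(baseline, (n_samples, 1))
    log_rfu += np.outer(cent.astype(float), np.log(fc))
    log_rfu += np.outer(sex.astype(float), sex_coef)
    log_rfu += np.outer(year - year.mean(), year_coef)
    # module latent factors, shared sign within module
    for mi in range(1, len(module_sizes) + 1):
        members = np.flatnonzero(module_assignment == f"M{mi}")
        latent = rng.normal(0.0, 1.0, size=n_samples)
        loadings = np.abs(rng.normal(config.module_latent_sd,
                                     config.module_latent_sd / 4, len(members)))
        log_rfu[:, members] += np.outer(latent, loadings)
    long_ind = (surv_class == "long").astype(float)
    log_rfu += np.outer(long_ind, surv_effect)
    log_rfu += rng.normal(0.0, config.residual_sd_log, size=(n_samples, m))

    expression = pd.DataFrame(np.exp(log_rfu), index=samples.index,
                              columns=aptamers.index)

    truth = TruthLedger(
        planted_direction=pd.Series(direction, index=aptamers.index),
        planted_fc=pd.Series(fc, index=aptamers.index),
        module_assignment=pd.Series(module_assignment, index=aptamers.index),
        survival_effect=pd.Series(surv_effect, index=aptamers.index),
        group_of_sample=samples["group"].copy(),
        survival_class_of_sample=pd.Series(surv_class, index=samples.index),
    )
    return expression, samples, aptamers, truth


def simulate_external_study(
    truth: TruthLedger,
    n_samples: int,
    attenuation: float,
    noise_sd: float,
    seed: int,
    overlap: list | None = None,
) -> pd.DataFrame:
    """Summary table of an independent aging study sharing the platform.

    Per aptamer the study observes a signed z-score centered on the
    attenuation-scaled planted log fold change:

        z_j ~ N( attenuation * log(fc_j) * sqrt(n) / noise_sd, 1 )

    and reports effect_sign = sign(z), p = two-sided normal tail, and
    n_samples.  ``overlap`` restricts to a platform-intersection list.
    attenuation = 0 yields an exact null study (uniform p).
    """
    if not 0 <= attenuation <= 1:
        raise ValueError("attenuation must be in [0, 1]")
    if noise_sd <= 0 or n_samples <= 0:
        raise ValueError("noise_sd and n_samples must be positive")
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    ids = truth.planted_fc.index
    if overlap is not None:
        ids = ids.intersection(pd.Index(overlap))
    mu = attenuation * np.log(truth.planted_fc.loc[ids].to_numpy()) \
        * np.sqrt(n_samples) / noise_sd
    z = mu + rng.standard_normal(len(ids))
    p = 2.0 * sps.norm.sf(np.abs(z))
    return pd.DataFrame({
        "aptamer_id": ids,
        "effect_sign": np.where(z >= 0, 1, -1),
        "p_value": p,
        "n_samples": n_samples,
    }).set_index("aptamer_id")


def make_fixture_gene_sets(
    truth: TruthLedger,
    n_sets: int,
    set_size_range: tuple,
    contamination: float,
    seed: int,
) -> dict[str, set]:
    """Fixture gene-set collection (GMT-serializable) tied to the truth.

    Emits sets enriched for planted-up genes, planted-down genes, and
    each planted module, plus random decoys, cycling through those
    flavors until ``n_sets`` sets exist.  ``contamination`` is the
    fraction of each set replaced by random platform genes; at 1 the
    sets are independent of the truth.
    """
    if not 0 <= contamination <= 1:
        raise ValueError("contamination must be in [0, 1]")
    rng = np.random.default_rng(seed)
    # the ledger does not carry gene symbols, so sets are keyed by aptamer
    # id; callers holding an aptamer table can map ids to symbols afterwards
    universe = truth.planted_fc.index.to_numpy()
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set sizes exceed the number of available genes")
    pools = [universe[(truth.planted_direction == "up").to_numpy()],
             universe[(truth.planted_direction == "down").to_numpy()]]
    for mod in sorted(set(truth.module_assignment) - {"unassigned"}):
        pools.append(universe[(truth.module_assignment == mod).to_numpy()])
    pools.append(None)  # decoy flavor

    collection: dict[str, set] = {}
    flavor_names = ["up", "down"] + \
        [m for m in sorted(set(truth.module_assignment) - {"unassigned"})] + ["decoy"]
    for i in range(n_sets):
        flavor = i % len(pools)
        size = int(rng.integers(lo, hi + 1))
        pool = pools[flavor]
        if pool is None or len(pool) == 0:
            members = rng.choice(universe, size=size, replace=False)
        else:
            n_true = int(round(size * (1 - contamination)))
            n_true = min(n_true, len(pool))
            members = list(rng.choice(pool, size=n_true, replace=False))
            if size - n_true > 0:
                rest = np.setdiff1d(universe, np.array(members, dtype=object))
                members += list(rng.choice(rest, size=size - n_true,
                                           replace=False))
            members = np.array(members, dtype=object)
        collection[f"SET_{i + 1}_{flavor_names[flavor]}"] = set(members)
    return collection
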