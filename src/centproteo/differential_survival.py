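"""Differential-abundance and survival signatures.

The headline analysis: a covariate-adjusted ANOVA F test per aptamer on
log-RFU across the three groups, Benjamini-Hochberg control at 1% FDR,
fold changes in the control-vs-centenarian orientation (FC > 1 means
the protein is lower in centenarians), an offspring-vs-control
two-group contrast, survival signatures from dichotomized follow-up
(2-year cutoff in centenarians, 10-year cutoff in the younger groups),
and sign-quadrant classification of paired signatures (e.g. the
delayed-aging pattern: proteins that rise with age but sit lower in
centenarians' offspring than in controls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Study
from .stats_core import batch_anova_f, batch_binary_adjusted, bh_adjust

__all__ = [
    "SurvivalLabeling",
    "compute_fold_change",
    "centenarian_signature",
    "offspring_control_contrast",
    "label_survival",
    "survival_signature",
    "expected_count_ratio",
    "direction_pattern",
]

CENTENARIAN_CUTOFF_YEARS = 2.0
YOUNGER_CUTOFF_YEARS = 10.0


def _covariate_design(samples: pd.DataFrame, columns: tuple) -> np.ndarray:
    """Numeric covariate columns: sex as 0/1, years as given, type as 0/1."""
    cols = []
    for c in columns:
        if c == "sex":
            cols.append((samples["sex"] == "F").astype(float).to_numpy())
        elif c == "participant_type":
            cols.append((samples["group"] == "offspring").astype(float).to_numpy())
        else:
            if c not in samples.columns:
                raise ValueError(f"missing covariate column: {c}")
            vals = samples[c].astype(float).to_numpy()
            if np.any(~np.isfinite(vals)):
                raise ValueError(f"covariate column {c} has missing values")
            cols.append(vals)
    return np.column_stack(cols)


def compute_fold_change(expression: pd.DataFrame, samples: pd.DataFrame,
                        numerator_group: str, denominator_group: str) -> pd.Series:
    """Ratio of geometric means: exp(mean log num - mean log den), per aptamer."""
    num = samples.index[samples["group"] == numerator_group]
    den = samples.index[samples["group"] == denominator_group]
    if len(num) == 0 or len(den) == 0:
        raise ValueError(
            f"empty group in fold change: {numerator_group}={len(num)}, "
            f"{denominator_group}={len(den)}")
    logx = np.log(expression)
    return np.exp(logx.loc[num].mean(axis=0) - logx.loc[den].mean(axis=0))


def _adjusted_group_differences(logx: np.ndarray, samples: pd.DataFrame,
                                covariates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Adjusted centenarian-minus-control and centenarian-minus-offspring
    log-RFU differences per aptamer, from the full OLS fit."""
    n = len(samples)
    is_off = (samples["group"] == "offspring").astype(float).to_numpy()
    is_ctl = (samples["group"] == "control").astype(float).to_numpy()
    X = np.column_stack([np.ones(n), covariates, is_off, is_ctl])
    beta, *_ = np.linalg.lstsq(X, logx, rcond=None)
    diff_vs_off = -beta[-2]  # cent is reference level
    diff_vs_ctl = -beta[-1]
    return diff_vs_ctl, diff_vs_off


def centenarian_signature(study: Study, fdr: float = 0.01,
                          covariates: tuple = ("sex", "collection_year")) -> dict:
    """Three-group differential signature at the given FDR.

    Per aptamer: ANOVA F on log-RFU adjusted for sex and collection
    year; BH across all aptamers; signature = {q < fdr}.  Direction is
    "up_in_centenarians" only when the adjusted centenarian mean exceeds
    both younger groups' (both Table-style fold changes < 1), "down"
    when below both, "mixed" otherwise (mixed aptamers are excluded
    from the up/down sets).

    Returns a dict with the per-aptamer records table, the up/down/mixed
    aptamer id sets, and aptamer/unique-protein counts.
    """
    groups = set(study.samples["group"])
    if groups != {"centenarian", "offspring", "control"}:
        raise ValueError(f"need all three groups, got {sorted(groups)}")
    logx = study.log_rfu().to_numpy()
    cov = _covariate_design(study.samples, covariates)
    F, p, _ = batch_anova_f(logx, study.samples["group"].to_numpy(), cov)
    q = bh_adjust(p)
    fc_cont = compute_fold_change(study.expression, study.samples,
                                  "control", "centenarian")
    fc_off = compute_fold_change(study.expression, study.samples,
                                 "offspring", "centenarian")
    d_ctl, d_off = _adjusted_group_differences(logx, study.samples, cov)
    direction = np.where((d_ctl > 0) & (d_off > 0), "up_in_centenarians",
                         np.where((d_ctl < 0) & (d_off < 0),
                                  "down_in_centenarians", "mixed"))
    records = pd.DataFrame({
        "aptamer_id": study.expression.columns,
        "gene_symbol": study.aptamers["gene_symbol"].to_numpy(),
        "F": F,
        "p": p,
        "q": q,
        "fc_cont_vs_cent": fc_cont.to_numpy(),
        "fc_off_vs_cent": fc_off.to_numpy(),
        "effect": d_ctl,  # adjusted centenarian-vs-control log difference
        "direction": direction,
    }).set_index("aptamer_id")
    selected = records.index[records["q"] < fdr]
    sig = records.loc[selected]
    up = set(sig.index[sig["direction"] == "up_in_centenarians"])
    down = set(sig.index[sig["direction"] == "down_in_centenarians"])
    mixed = set(sig.index[sig["direction"] == "mixed"])
    n_proteins = study.aptamers.loc[list(selected), "gene_symbol"].nunique()
    return {
        "records": records,
        "signature": set(selected),
        "up": up,
        "down": down,
        "mixed": mixed,
        "n_aptamers": len(selected),
        "n_unique_proteins": int(n_proteins),
    }


def offspring_control_contrast(study: Study,
                               covariates: tuple = ("sex", "collection_year"),
                               nominal_alpha: float = 0.05) -> dict:
    """Offspring-vs-control adjusted two-group test per aptamer.

    Mirrors the signature schema minus the centenarian group; also
    returns the nominal p < 0.05 aptamer list consumed by the
    delayed-aging pattern analysis.
    """
    mask = study.samples["group"].isin(["offspring", "control"])
    samples = study.samples.loc[mask]
    if samples["group"].nunique() < 2:
        raise ValueError("both offspring and control groups required")
    logx = study.log_rfu().loc[samples.index].to_numpy()
    cov = _covariate_design(samples, covariates)
    ind = (samples["group"] == "offspring").astype(float).to_numpy()
    t, p, coef = batch_binary_adjusted(logx, ind, cov)
    q = bh_adjust(p)
    expr_sub = study.expression.loc[samples.index]
    fc = compute_fold_change(expr_sub, samples, "control", "offspring")
    records = pd.DataFrame({
        "aptamer_id": study.expression.columns,
        "gene_symbol": study.aptamers["gene_symbol"].to_numpy(),
        "t": t,
        "p": p,
        "q": q,
        "fc_cont_vs_off": fc.to_numpy(),
        "effect": coef,  # adjusted offspring-minus-control log difference
        "direction": np.where(coef > 0, "up_in_offspring",
                              np.where(coef < 0, "down_in_offspring", "zero")),
    }).set_index("aptamer_id")
    return {
        "records": records,
        "significant_fdr01": set(records.index[records["q"] < 0.01]),
        "nominal": set(records.index[records["p"] < nominal_alpha]),
    }


@dataclass
class SurvivalLabeling:
    """short/long/unlabeled per sample, with the per-group cutoffs used."""

    labels: pd.Series
    cutoff_years: dict

    def labeled(self, sample_ids) -> pd.Series:
        sub = self.labels.loc[sample_ids]
        return sub[sub != "unlabeled"]


def label_survival(samples: pd.DataFrame) -> SurvivalLabeling:
    """Dichotomize survival follow-up per the study's group cutoffs.

    Centenarians: short iff died with survival < 2 years; long iff
    survival >= 2 years (dead or alive).  Offspring/controls: short iff
    died within <= 10 years; long iff survival > 10 years; alive with
    follow-up not yet past 10 years -> unlabeled.  Samples without
    follow-up are unlabeled.
    """
    years = samples["survival_years"].astype(float)
    if (years.dropna() < 0).any():
        bad = samples.index[years < 0].tolist()
        raise ValueError(f"negative survival time for samples: {bad[:10]}")
    dead = samples["dead"].astype(bool)
    cent = samples["group"] == "centenarian"
    labels = pd.Series("unlabeled", index=samples.index, dtype=object)
    known = years.notna()
    # centenarians: boundary closed on long ("2 years or more")
    labels[cent & known & (years >= CENTENARIAN_CUTOFF_YEARS)] = "long"
    labels[cent & known & dead & (years < CENTENARIAN_CUTOFF_YEARS)] = "short"
    # younger groups: death at exactly 10.0 years counts as short
    labels[~cent & known & dead & (years <= YOUNGER_CUTOFF_YEARS)] = "short"
    labels[~cent & known & (years > YOUNGER_CUTOFF_YEARS)] = "long"
    return SurvivalLabeling(labels, {
        "centenarian": CENTENARIAN_CUTOFF_YEARS,
        "offspring": YOUNGER_CUTOFF_YEARS,
        "control": YOUNGER_CUTOFF_YEARS,
    })


def survival_signature(study: Study, labeling: SurvivalLabeling,
                       subgroup: str, alpha: float = 0.005) -> dict:
    """Per-aptamer adjusted association with the long/short survival class.

    subgroup "centenarians": covariates sex + age at draw.  subgroup
    "younger" (offspring and controls pooled): sex + age at draw +
    participant type.  Selection at nominal p < alpha; BH q and the
    long-vs-short fold change are reported for every aptamer.
    """
    if subgroup == "centenarians":
        mask = study.samples["group"] == "centenarian"
        covs = ("sex", "age_at_draw")
    elif subgroup == "younger":
        mask = study.samples["group"].isin(["offspring", "control"])
        covs = ("sex", "age_at_draw", "participant_type")
    else:
        raise ValueError("subgroup must be 'centenarians' or 'younger'")
    sub = study.samples.loc[mask]
    lab = labeling.labeled(sub.index)
    if lab.nunique() < 2 or (lab == "long").sum() < 2 or (lab == "short").sum() < 2:
        raise ValueError(
            f"need >= 2 labeled samples per survival class in {subgroup}")
    keep = lab.index
    samples = sub.loc[keep]
    logx = study.log_rfu().loc[keep].to_numpy()
    cov = _covariate_design(samples, covs)
    ind = (lab == "long").astype(float).to_numpy()
    t, p, coef = batch_binary_adjusted(logx, ind, cov)
    q = bh_adjust(p)
    # adjusted fold change: exp of the model coefficient, so its sign is
    # consistent with the reported effect by construction
    records = pd.DataFrame({
        "aptamer_id": study.expression.columns,
        "gene_symbol": study.aptamers["gene_symbol"].to_numpy(),
        "t": t,
        "p": p,
        "q": q,
        "effect": coef,
        "fc_long_vs_short": np.exp(coef),
    }).set_index("aptamer_id")
    selected = set(records.index[records["p"] < alpha])
    return {
        "records": records,
        "signature": selected,
        "n_selected": len(selected),
        "n_long": int((lab == "long").sum()),
        "n_short": int((lab == "short").sum()),
        "expected_by_chance": alpha * len(records),
    }


def expected_count_ratio(n_selected: int, m: int, alpha: float) -> float:
    """Observed selections over the count expected by chance (m * alpha)."""
    if m <= 0:
        raise ValueError("m must be positive")
    return n_selected / (m * alpha)


def direction_pattern(signature_a: dict, signature_b: dict) -> dict:
    """Sign-quadrant classification of two signed-effect maps.

    Each aptamer present in both maps lands in one of four quadrants by
    the signs of its effects (a+/b+, a+/b-, a-/b+, a-/b-); exact zeros
    are tallied separately.  Returns quadrant counts and membership.
    """
    shared = sorted(set(signature_a) & set(signature_b))
    quadrants = {"a+/b+": set(), "a+/b-": set(), "a-/b+": set(), "a-/b-": set(),
                 "zero": set()}
    for k in shared:
        ea, eb = signature_a[k], signature_b[k]
        if ea == 0 or eb == 0:
            quadrants["zero"].add(k)
            continue
        key = f"a{'+' if ea > 0 else '-'}/b{'+' if eb > 0 else '-'}"
        quadrants[key].add(k)
    return {
        "counts": {k: len(v) for k, v in quadrants.items()},
        "members": quadrants,
        "n_shared": len(shared),
    }
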