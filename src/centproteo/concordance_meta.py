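"""Cross-study concordance, signature derivation and meta-analysis.

An external aging study reports, per protein, an effect sign, a
p-value and a sample size.  On the platform intersection both studies
are re-adjusted with Benjamini-Hochberg and each result is assigned a
significance tier — significant (q below the FDR cut), not significant
(p > 0.2) or ambiguous (between).  The tier cross-table yields the
replicated set (significant in both, concordant sign), the
extreme-old-age signature (significant here, clearly flat with age in
the external cohort) and the immune-senescence signature (ages in the
external cohort, flat here).  Aptamers with p < 0.2 in both studies are
combined by weighted Stouffer meta-analysis (weights sqrt(n)).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats_core import ContingencyTable2x2, bh_adjust, fisher_exact_2x2, stouffer_meta

logger = logging.getLogger("centproteo")

TIERS = ("significant", "ambiguous", "not_significant")

__all__ = [
    "assign_tier",
    "cross_classify",
    "sign_concordance_test",
    "derive_signatures",
    "meta_analyze",
    "replication_union",
    "filter_interval_style",
]


def assign_tier(p: float, q: float, fdr: float = 0.01, p_ns: float = 0.2) -> str:
    """Three-way significance tier: q < fdr > p > 0.2 partition."""
    if not (0 <= p <= 1 and 0 <= q <= 1):
        raise ValueError("p and q must be in [0, 1]")
    if q < fdr:
        return "significant"
    if p > p_ns:
        return "not_significant"
    return "ambiguous"


def _tier_vector(p: np.ndarray, fdr: float, p_ns: float) -> np.ndarray:
    """Tier every entry after recomputing BH within the given vector."""
    q = bh_adjust(p)
    return np.array([assign_tier(pi, qi, fdr, p_ns) for pi, qi in zip(p, q)],
                    dtype=object)


def _align(internal: pd.DataFrame, external: pd.DataFrame):
    """Restrict both record tables to their shared keys (sorted)."""
    shared = internal.index.intersection(external.index).sort_values()
    if len(shared) == 0:
        raise ValueError("no shared aptamers between internal and external study")
    return internal.loc[shared], external.loc[shared]


def cross_classify(internal: pd.DataFrame, external: pd.DataFrame,
                   fdr: float = 0.01, p_ns: float = 0.2) -> dict:
    """3x3 tier cross-table on the platform intersection.

    BH is recomputed within the intersection for both studies so the
    tiers are well-defined on the compared universe.  ``internal``
    needs columns p (and effect for downstream sign use); ``external``
    needs p_value.
    """
    internal, external = _align(internal, external)
    t_int = _tier_vector(internal["p"].to_numpy(), fdr, p_ns)
    t_ext = _tier_vector(external["p_value"].to_numpy(), fdr, p_ns)
    table = pd.DataFrame(0, index=pd.Index(TIERS, name="internal"),
                         columns=pd.Index(TIERS, name="external"))
    for ti, te in zip(t_int, t_ext):
        table.loc[ti, te] += 1
    assert int(table.to_numpy().sum()) == len(internal)
    return {
        "table": table,
        "internal_tier": pd.Series(t_int, index=internal.index),
        "external_tier": pd.Series(t_ext, index=external.index),
        "n_overlap": len(internal),
    }


def sign_concordance_test(membership: pd.Series, concordant: pd.Series) -> dict:
    """Fisher exact test of sign concordance vs signature membership.

    2x2 of (in signature) x (signs agree) over the shared keys; the
    per-stratum concordance rates accompany the test.
    """
    keys = membership.index.intersection(concordant.index)
    m = membership.loc[keys].astype(bool)
    c = concordant.loc[keys].astype(bool)
    a = int((m & c).sum())
    b = int((m & ~c).sum())
    cc = int((~m & c).sum())
    d = int((~m & ~c).sum())
    result, odds = fisher_exact_2x2(ContingencyTable2x2(a, b, cc, d))
    return {
        "test": result,
        "odds_ratio": odds,
        "rate_in_signature": a / max(a + b, 1),
        "rate_out_signature": cc / max(cc + d, 1),
        "table": ContingencyTable2x2(a, b, cc, d),
    }


def derive_signatures(internal: pd.DataFrame, external: pd.DataFrame,
                      fdr: float = 0.01, p_ns: float = 0.2) -> dict:
    """Replicated / extreme-old-age / immune-senescence sets from tiers.

    replicated: significant in both with equal sign; discordant-sign
    jointly significant aptamers are reported separately.
    extreme_old_age: internal-significant x external-not-significant.
    immune_senescence: external-significant x internal-not-significant.
    The three sets are pairwise disjoint by construction.
    """
    cc = cross_classify(internal, external, fdr, p_ns)
    internal, external = _align(internal, external)
    ti, te = cc["internal_tier"], cc["external_tier"]
    sign_int = np.sign(internal["effect"].to_numpy())
    sign_ext = external["effect_sign"].to_numpy()
    both_sig = (ti == "significant") & (te == "significant")
    same_sign = pd.Series(sign_int == sign_ext, index=internal.index)
    replicated = set(internal.index[both_sig & same_sign])
    discordant = set(internal.index[both_sig & ~same_sign])
    extreme = set(internal.index[(ti == "significant") & (te == "not_significant")])
    immune = set(internal.index[(te == "significant") & (ti == "not_significant")])
    assert not (replicated & extreme or replicated & immune or extreme & immune)
    return {
        "replicated": replicated,
        "extreme_old_age": extreme,
        "immune_senescence": immune,
        "discordant_significant": discordant,
        "crosstab": cc["table"],
    }


def _signed_z(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), 1e-300, 1.0)
    return np.asarray(sign, dtype=float) * sps.norm.isf(p / 2.0)


def meta_analyze(internal: pd.DataFrame, external: pd.DataFrame,
                 n_internal: int, p_max: float = 0.2,
                 fdr: float = 0.01) -> dict:
    """Stouffer meta-analysis of aptamers nominally supported in both studies.

    Restricts to p < p_max in both; converts each study to a signed z
    (z = sign * Phi^-1(1 - p/2)); combines with weights sqrt(n); BH
    within the restricted set; returns records and the set significant
    at the given FDR.  ``external`` must carry n_samples.
    """
    if "n_samples" not in external.columns:
        raise ValueError("external study must report n_samples")
    internal, external = _align(internal, external)
    mask = (internal["p"].to_numpy() < p_max) & \
           (external["p_value"].to_numpy() < p_max)
    keys = internal.index[mask]
    if len(keys) == 0:
        return {"records": pd.DataFrame(), "significant": set(), "n_restricted": 0}
    z_int = _signed_z(internal.loc[keys, "p"],
                      np.sign(internal.loc[keys, "effect"]))
    z_ext = _signed_z(external.loc[keys, "p_value"],
                      external.loc[keys, "effect_sign"])
    n_ext = external.loc[keys, "n_samples"].to_numpy(dtype=float)
    w_int = np.sqrt(float(n_internal))
    w_ext = np.sqrt(n_ext)
    z_meta = np.array([
        stouffer_meta(np.array([zi, ze]), np.array([w_int, we])).statistic
        for zi, ze, we in zip(z_int, z_ext, w_ext)
    ])
    p_meta = 2.0 * sps.norm.sf(np.abs(z_meta))
    q_meta = bh_adjust(p_meta)
    records = pd.DataFrame({
        "z_internal": z_int, "z_external": z_ext,
        "z_meta": z_meta, "p": p_meta, "q": q_meta,
    }, index=keys)
    return {
        "records": records,
        "significant": set(keys[q_meta < fdr]),
        "n_restricted": len(keys),
    }


def replication_union(per_study_sets: dict[str, set]) -> dict:
    """Union of per-study replicated sets with provenance flags."""
    union: dict[str, set] = {}
    for study, members in per_study_sets.items():
        for k in members:
            union.setdefault(k, set()).add(study)
    provenance = pd.Series({k: sorted(v) for k, v in union.items()},
                           dtype=object).sort_index()
    return {
        "union": set(union),
        "provenance": provenance,
        "n_aptamers": len(union),
    }


def filter_interval_style(external: pd.DataFrame,
                          consistency_reference: pd.DataFrame,
                          fdr: float = 0.01) -> pd.DataFrame:
    """Sign-consistency and significance filter for an external study.

    Drops aptamers whose sign disagrees with a second reference study's
    sign, and aptamers not significant within the external study (BH q
    recomputed over the external table).  The surviving records feed the
    concordance analysis.
    """
    ext = external.copy()
    ext["q"] = bh_adjust(ext["p_value"].to_numpy())
    shared_ref = ext.index.intersection(consistency_reference.index)
    ref_sign = consistency_reference.loc[shared_ref, "effect_sign"]
    inconsistent = shared_ref[ext.loc[shared_ref, "effect_sign"].to_numpy()
                              != ref_sign.to_numpy()]
    keep = ext.index.difference(inconsistent)
    kept = ext.loc[keep]
    kept = kept[kept["q"] < fdr]
    logger.info("interval-style filter: %d -> %d aptamers", len(ext), len(kept))
    return kept.sort_index()
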