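"""Gene-set over-representation and per-sample pathway projection.

Over-representation is a two-sided Fisher exact test of target-set
membership against gene-set membership over an explicit protein
universe (the full annotated platform, e.g. its ~4100 unique proteins),
with Benjamini-Hochberg adjustment across the collection.  Pathway
projection scores each sample on each gene set as the mean of the
members' z-standardized log-RFU profiles; pathway scores then run
through the same covariate-adjusted group or survival tests as single
proteins.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import Study
from .stats_core import (ContingencyTable2x2, batch_anova_f,
                         batch_binary_adjusted, bh_adjust, fisher_exact_2x2)

logger = logging.getLogger("centproteo")

__all__ = ["enrich", "project_pathways", "pathway_differential"]


def enrich(target: set, collection: dict[str, set], universe: set) -> pd.DataFrame:
    """Fisher-exact over-representation of ``target`` in each set.

    Sets are intersected with the universe before testing; the target
    must be a subset of the universe.  Returns one row per set with the
    2x2 counts, odds ratio, two-sided p and BH q (sorted by p).
    """
    if not universe:
        raise ValueError("empty universe")
    target = set(target)
    if not target <= set(universe):
        stray = sorted(target - set(universe))[:5]
        raise ValueError(f"target contains genes outside the universe: {stray}")
    universe = set(universe)
    rows = []
    for name, members in collection.items():
        inset = members & universe
        a = len(target & inset)
        b = len(target) - a
        c = len(inset) - a
        d = len(universe) - len(target) - c
        res, odds = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        rows.append({
            "set_name": name,
            "overlap": a,
            "set_size_in_universe": len(inset),
            "target_size": len(target),
            "universe_size": len(universe),
            "odds_ratio": odds,
            "p": res.p_value,
        })
    out = pd.DataFrame(rows).set_index("set_name")
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "set_name"], kind="mergesort")
    return out


def project_pathways(study: Study, collection: dict[str, set],
                     min_members: int = 5) -> dict:
    """Per-sample pathway scores: mean of member z-profiles.

    Each aptamer's log-RFU is z-standardized across samples; a pathway
    score is the mean z over the aptamers whose gene symbol belongs to
    the set.  Pathways with fewer than ``min_members`` platform members
    are dropped with a warning.
    """
    if not collection:
        raise ValueError("empty gene-set collection")
    logx = study.log_rfu()
    z = (logx - logx.mean(axis=0)) / logx.std(axis=0, ddof=1).replace(0, np.nan)
    z = z.fillna(0.0)
    symbol_of = study.aptamers["gene_symbol"]
    scores = {}
    counts = {}
    for name, members in collection.items():
        member_apts = symbol_of.index[symbol_of.isin(members)]
        if len(member_apts) < min_members:
            logger.warning("pathway %r has %d platform members (< %d); dropped",
                           name, len(member_apts), min_members)
            continue
        scores[name] = z[member_apts].mean(axis=1)
        counts[name] = len(member_apts)
    return {
        "scores": pd.DataFrame(scores, index=logx.index),
        "member_counts": counts,
    }


def pathway_differential(scores: pd.DataFrame, study: Study,
                         design: str = "three_group",
                         labeling=None, subgroup: str = "centenarians",
                         fdr: float = 0.05) -> pd.DataFrame:
    """Group or survival differential test on each pathway score.

    design "three_group": ANOVA F adjusted for sex and collection year,
    direction from the adjusted centenarian-vs-others difference.
    design "survival": the same adjusted two-class t test used for
    single proteins on the labeled subgroup (needs ``labeling``).
    BH across pathways; "significant" flags q < fdr.
    """
    from .differential_survival import _covariate_design

    if scores.shape[1] == 0:
        raise ValueError("no pathway scores to test")
    if design == "three_group":
        samples = study.samples.loc[scores.index]
        cov = _covariate_design(samples, ("sex", "collection_year"))
        stat, p, effect = batch_anova_f(scores.to_numpy(),
                                        samples["group"].to_numpy(), cov)
    elif design == "survival":
        if labeling is None:
            raise ValueError("survival design requires a SurvivalLabeling")
        if subgroup == "centenarians":
            mask = study.samples["group"] == "centenarian"
            covs = ("sex", "age_at_draw")
        else:
            mask = study.samples["group"].isin(["offspring", "control"])
            covs = ("sex", "age_at_draw", "participant_type")
        sub = study.samples.loc[mask]
        lab = labeling.labeled(sub.index)
        samples = sub.loc[lab.index]
        cov = _covariate_design(samples, covs)
        ind = (lab == "long").astype(float).to_numpy()
        stat, p, effect = batch_binary_adjusted(
            scores.loc[lab.index].to_numpy(), ind, cov)
    else:
        raise ValueError("design must be 'three_group' or 'survival'")
    q = bh_adjust(p)
    out = pd.DataFrame({
        "statistic": stat,
        "p": p,
        "q": q,
        "effect": effect,
        "direction": np.where(effect > 0, "up", np.where(effect < 0, "down", "zero")),
        "significant": q < fdr,
    }, index=scores.columns)
    return out.sort_values(["p"], kind="mergesort")
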