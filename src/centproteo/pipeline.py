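"""End-to-end orchestration: QC -> differential -> survival -> concordance
-> enrichment -> projection -> network, from a run configuration.

A run consumes either a study on disk (expression/samples/aptamers TSV
triplet) or a simulation config, applies sample QC, executes every
analysis stage with the configured thresholds, writes one TSV per stage
plus a machine-readable summary JSON, and is bit-for-bit reproducible
from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance_meta import (cross_classify, derive_signatures,
                               filter_interval_style, meta_analyze,
                               replication_union, sign_concordance_test)
from .differential_survival import (centenarian_signature, direction_pattern,
                                    expected_count_ratio, label_survival,
                                    offspring_control_contrast,
                                    survival_signature)
from .enrichment_projection import enrich, pathway_differential, project_pathways
from .io_formats import Study, load_study, read_gene_sets, write_results
from .network import (build_module_graph, detect_modules, module_eigengene,
                      module_group_difference, soft_threshold_select,
                      topological_overlap, correlation_matrix)
from .synthetic_data import (SimulationConfig, make_fixture_gene_sets,
                             simulate_cohort, simulate_external_study)

logger = logging.getLogger("centproteo")

__all__ = ["RunConfig", "qc_outlier_samples", "run_full_analysis", "score_truth"]


@dataclass
class RunConfig:
    """Thresholds and inputs of one full analysis run."""

    expression_path: str | None = None
    samples_path: str | None = None
    aptamers_path: str | None = None
    gene_sets_path: str | None = None
    external_path: str | None = None
    simulate: dict | None = None      # SimulationConfig overrides
    fdr: float = 0.01
    p_ns: float = 0.2
    survival_alpha: float = 0.005
    pathway_fdr: float = 0.05
    me_cor: float = 0.8
    jaccard: float = 0.10
    min_module_size: int = 20
    network_top_aptamers: int = 1500  # most-variable subset for the network stage
    qc_z_cut: float = 5.0
    seed: int = 0
    out_dir: str = "centproteo_out"

    def validate(self) -> None:
        for name, v in (("fdr", self.fdr), ("p_ns", self.p_ns),
                        ("survival_alpha", self.survival_alpha),
                        ("pathway_fdr", self.pathway_fdr),
                        ("jaccard", self.jaccard)):
            if not 0 < v < 1:
                raise ValueError(f"threshold {name}={v} outside (0, 1)")
        if not 0 < self.me_cor < 1:
            raise ValueError("me_cor must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        has_files = all((self.expression_path, self.samples_path,
                         self.aptamers_path))
        if not has_files and self.simulate is None:
            raise ValueError("provide either input paths or a simulation config")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        # out_dir does not affect the analysis, so it is not hashed
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:12]


def qc_outlier_samples(study: Study, z_cut: float = 5.0):
    """Remove samples whose mean correlation to the rest is an outlier.

    Each sample's mean Pearson correlation (log-RFU, across aptamers) to
    all other samples is scored with a robust z (median/MAD); samples
    with z < -z_cut are removed and the criterion is re-evaluated once.
    Aborts rather than remove more than 10% of samples.
    """
    if study.n_samples < 10:
        raise ValueError("QC needs at least 10 samples")
    removed: list[str] = []
    current = study
    for _pass in range(2):
        logx = np.log(current.expression.to_numpy())
        corr = np.corrcoef(logx)
        np.fill_diagonal(corr, np.nan)
        mean_corr = np.nanmean(corr, axis=1)
        med = np.median(mean_corr)
        mad = np.median(np.abs(mean_corr - med))
        scale = 1.4826 * mad if mad > 0 else np.std(mean_corr) or 1.0
        z = (mean_corr - med) / scale
        bad = current.expression.index[z < -z_cut]
        if len(bad) == 0:
            break
        removed.extend(bad.tolist())
        if len(removed) > 0.10 * study.n_samples:
            raise RuntimeError(
                f"QC would remove {len(removed)} of {study.n_samples} samples "
                "(> 10%); inspect the data instead")
        keep = current.expression.index.difference(bad)
        current = Study(current.expression.loc[keep],
                        current.samples.loc[keep], current.aptamers)
        logger.info("QC removed outlier samples: %s", sorted(bad))
    return current, removed


def _network_stage(study: Study, config: RunConfig, rng_seedless: bool = True):
    """Module detection in each group layer + the cross-group graph."""
    log_var = np.log(study.expression).var(axis=0)
    top = log_var.sort_values(ascending=False).index[: config.network_top_aptamers]
    top = top.sort_values()
    layers = {}
    for label, groups in (("centenarian", ["centenarian"]),
                          ("offspring_control", ["offspring", "control"])):
        samp = study.samples.index[study.samples["group"].isin(groups)]
        corr = correlation_matrix(study.expression[top], samp)
        sel = soft_threshold_select(corr)
        tom = topological_overlap(sel["adjacency"])
        modules = detect_modules(tom, config.min_module_size, corr=corr,
                                 group=label)
        eig = {}
        for mid, members in modules.memberships.items():
            eig[mid] = module_eigengene(study.expression, members, samp)
            modules.avg_std_diff[mid] = module_group_difference(
                study.expression, members, study.samples, groups)
        if eig:
            modules.eigengenes = pd.DataFrame(eig)
        layers[label] = {"modules": modules, "power": sel["power"]}
    graph = build_module_graph(layers["centenarian"]["modules"],
                               layers["offspring_control"]["modules"],
                               config.me_cor, config.jaccard)
    return layers, graph


def _graph_to_json(graph) -> dict:
    nodes = [{"group": g, "module": m, **data}
             for (g, m), data in graph.nodes(data=True)]
    edges = [{"source": list(u), "target": list(v), **data}
             for u, v, data in graph.edges(data=True)]
    return {"nodes": nodes, "edges": edges}


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to config.out_dir.

    Returns the in-memory bundle: stage results plus run metadata.
    Stages that lack their inputs (external study, survival follow-up,
    gene sets) are skipped and flagged in the summary.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "skipped_stages": [],
    }
    bundle: dict = {"summary": summary}

    # --- inputs -------------------------------------------------------
    truth = None
    external = None
    external2 = None
    gene_sets = None
    if config.simulate is not None:
        sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
        expression, samples, aptamers, truth = simulate_cohort(sim)
        study = Study(expression.sort_index().sort_index(axis=1),
                      samples.sort_index(), aptamers.sort_index())
        external = simulate_external_study(
            truth, n_samples=240, attenuation=0.8, noise_sd=3.0,
            seed=config.seed + 1)
        # a second, larger partner study (rank-normalized platform style):
        # only effect signs are comparable, used for the consistency filter
        external2 = simulate_external_study(
            truth, n_samples=3301, attenuation=0.6, noise_sd=12.0,
            seed=config.seed + 3)
        gene_sets = make_fixture_gene_sets(
            truth, n_sets=50, set_size_range=(15, 200), contamination=0.2,
            seed=config.seed + 2)
        # fixture sets are keyed by aptamer id; map to gene symbols
        sym = aptamers["gene_symbol"]
        gene_sets = {name: set(sym.loc[sorted(m)]) for name, m in gene_sets.items()}
        bundle["truth"] = truth
    else:
        study = load_study(config.expression_path, config.samples_path,
                           config.aptamers_path)
        if config.external_path:
            external = pd.read_csv(config.external_path, sep="\t", index_col=0)
        if config.gene_sets_path:
            gene_sets = read_gene_sets(config.gene_sets_path)

    # --- QC -----------------------------------------------------------
    study, removed = qc_outlier_samples(study, config.qc_z_cut)
    summary["qc_removed_samples"] = removed
    bundle["study"] = study

    # --- differential -------------------------------------------------
    diff = centenarian_signature(study, fdr=config.fdr)
    write_results(diff["records"], out / "differential.tsv")
    summary["signature_aptamers"] = diff["n_aptamers"]
    summary["signature_unique_proteins"] = diff["n_unique_proteins"]
    summary["signature_up"] = len(diff["up"])
    summary["signature_down"] = len(diff["down"])
    summary["signature_mixed"] = len(diff["mixed"])
    bundle["differential"] = diff

    contrast = offspring_control_contrast(study)
    write_results(contrast["records"], out / "offspring_control.tsv")
    summary["offspring_control_fdr01"] = len(contrast["significant_fdr01"])
    summary["offspring_control_nominal"] = len(contrast["nominal"])
    bundle["offspring_control"] = contrast

    # delayed-aging pattern: age-direction (from centenarian signature)
    # vs offspring-vs-control direction among nominal aptamers
    nominal = sorted(contrast["nominal"] & diff["signature"])
    age_eff = diff["records"].loc[nominal, "effect"].to_dict()
    off_eff = contrast["records"].loc[nominal, "effect"].to_dict()
    pattern = direction_pattern(age_eff, off_eff)
    # delayed aging: change with age in centenarians, offspring shifted
    # opposite to controls' aging direction
    delayed = pattern["counts"]["a+/b-"] + pattern["counts"]["a-/b+"]
    summary["delayed_aging_aptamers"] = delayed
    bundle["delayed_aging_pattern"] = pattern

    # --- survival -----------------------------------------------------
    if study.samples["survival_years"].notna().any():
        labeling = label_survival(study.samples)
        bundle["survival"] = {}
        for subgroup in ("centenarians", "younger"):
            try:
                surv = survival_signature(study, labeling, subgroup,
                                          alpha=config.survival_alpha)
            except ValueError as exc:
                summary["skipped_stages"].append(f"survival_{subgroup}: {exc}")
                continue
            write_results(surv["records"], out / f"survival_{subgroup}.tsv")
            summary[f"survival_{subgroup}_selected"] = surv["n_selected"]
            summary[f"survival_{subgroup}_ratio_vs_chance"] = expected_count_ratio(
                surv["n_selected"], len(surv["records"]), config.survival_alpha)
            bundle["survival"][subgroup] = surv
    else:
        summary["skipped_stages"].append("survival: no follow-up data")

    # --- concordance / meta ------------------------------------------
    if external is not None:
        internal = diff["records"]
        cc = cross_classify(internal, external, config.fdr, config.p_ns)
        sigs = derive_signatures(internal, external, config.fdr, config.p_ns)
        meta = meta_analyze(internal, external, n_internal=study.n_samples,
                            p_max=config.p_ns, fdr=config.fdr)
        cc["table"].to_csv(out / "concordance_crosstab.tsv", sep="\t")
        summary["concordance_overlap"] = cc["n_overlap"]
        summary["crosstab"] = {
            f"{i}|{j}": int(cc["table"].loc[i, j])
            for i in cc["table"].index for j in cc["table"].columns}
        summary["replicated"] = len(sigs["replicated"])
        summary["extreme_old_age"] = len(sigs["extreme_old_age"])
        summary["immune_senescence"] = len(sigs["immune_senescence"])
        summary["meta_significant"] = len(meta["significant"])
        summary["meta_restricted"] = meta["n_restricted"]
        # sign concordance of signature membership vs external agreement
        shared = internal.index.intersection(external.index)
        membership = pd.Series(shared.isin(diff["signature"]), index=shared)
        concordant = pd.Series(
            np.sign(internal.loc[shared, "effect"]).to_numpy()
            == external.loc[shared, "effect_sign"].to_numpy(), index=shared)
        conc = sign_concordance_test(membership, concordant)
        summary["sign_concordance_p"] = conc["test"].p_value
        bundle["concordance"] = {"crosstab": cc, "signatures": sigs,
                                 "meta": meta, "sign_concordance": conc}
        # multi-study replication union, with the second study filtered
        # for sign consistency against the first
        per_study = {"study1": sigs["replicated"]}
        if external2 is not None:
            kept2 = filter_interval_style(external2, external,
                                          fdr=config.fdr)
            if len(kept2.index.intersection(internal.index)):
                sigs2 = derive_signatures(internal, kept2, config.fdr,
                                          config.p_ns)
                per_study["study2"] = sigs2["replicated"]
            else:
                summary["skipped_stages"].append(
                    "replication_study2: no aptamers survive the filter")
        union = replication_union(per_study)
        summary["replicated_union"] = union["n_aptamers"]
        bundle["replication_union"] = union
    else:
        summary["skipped_stages"].append("concordance: no external study")

    # --- enrichment and projection -----------------------------------
    if gene_sets:
        universe = set(study.aptamers["gene_symbol"])
        sig_proteins = set(study.aptamers.loc[sorted(diff["signature"]),
                                              "gene_symbol"])
        enr = enrich(sig_proteins, gene_sets, universe)
        write_results(enr, out / "enrichment_signature.tsv", sort_by=("p", "set_name"))
        summary["enriched_sets_fdr05"] = int((enr["q"] < 0.05).sum())
        bundle["enrichment"] = enr

        proj = project_pathways(study, gene_sets)
        pdiff = pathway_differential(proj["scores"], study,
                                     design="three_group", fdr=config.pathway_fdr)
        write_results(pdiff, out / "pathway_differential.tsv", sort_by=("p",))
        summary["pathways_tested"] = int(pdiff.shape[0])
        summary["pathways_significant"] = int(pdiff["significant"].sum())
        bundle["projection"] = {"scores": proj["scores"], "differential": pdiff}
    else:
        summary["skipped_stages"].append("enrichment: no gene sets")

    # --- network ------------------------------------------------------
    layers, graph = _network_stage(study, config)
    summary["modules_centenarian"] = len(layers["centenarian"]["modules"].memberships)
    summary["modules_offspring_control"] = len(
        layers["offspring_control"]["modules"].memberships)
    summary["null_module_centenarian"] = len(
        layers["centenarian"]["modules"].null_module)
    summary["cross_group_edges"] = sum(
        1 for *_e, d in graph.edges(data=True) if d["kind"] == "jaccard_overlap")
    with open(out / "module_graph.json", "w") as fh:
        json.dump(_graph_to_json(graph), fh, indent=1, sort_keys=True)
    membership_rows = []
    for label, layer in layers.items():
        for mid, members in layer["modules"].memberships.items():
            for a in sorted(members):
                membership_rows.append({"layer": label, "module": mid,
                                        "aptamer_id": a})
    write_results(pd.DataFrame(membership_rows,
                               columns=["layer", "module", "aptamer_id"]),
                  out / "module_membership.tsv", sort_by=())
    bundle["network"] = {"layers": layers, "graph": graph}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    return bundle


def score_truth(bundle: dict) -> dict:
    """Recovery metrics of a simulated run against its truth ledger."""
    truth = bundle.get("truth")
    if truth is None:
        raise ValueError("bundle has no truth ledger (not a simulated run)")
    diff = bundle["differential"]
    planted = set(truth.planted_direction.index[truth.planted_direction != "null"])
    detected = diff["signature"]
    tp = len(detected & planted)
    fp = len(detected - planted)
    sens = tp / len(planted) if planted else float("nan")
    fdr = fp / max(len(detected), 1)
    # direction agreement among detected planted aptamers
    det_planted = sorted(detected & planted)
    dir_map = {"up": "up_in_centenarians", "down": "down_in_centenarians"}
    truth_dir = truth.planted_direction.loc[det_planted].map(dir_map)
    obs_dir = diff["records"].loc[det_planted, "direction"]
    dir_acc = float((truth_dir == obs_dir).mean()) if det_planted else float("nan")
    out = {
        "n_planted": len(planted),
        "n_detected": len(detected),
        "sensitivity": sens,
        "empirical_fdr": fdr,
        "direction_accuracy": dir_acc,
    }
    surv = bundle.get("survival", {})
    planted_surv = set(truth.survival_effect.index[truth.survival_effect != 0])
    if planted_surv and surv:
        hits = set()
        for sub in surv.values():
            hits |= sub["signature"]
        out["survival_sensitivity"] = len(hits & planted_surv) / len(planted_surv)
    return out
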