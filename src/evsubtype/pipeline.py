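"""End-to-end orchestration of the two-stage analysis.

Stage 1 (screening cohort): quantification-limit censoring, the MWW
three-comparison screen plus two unsupervised random forests, and
candidate assembly.  Stage 2 (patient cohort): eligibility filtering,
MNAR imputation, consensus-clustering subtyping with PAC-based k
selection, subtype survival comparison (Kaplan-Meier / log-rank),
volcano marker discovery, median-split survival for fully quantified
markers, multivariate Cox regression, the curative-resection association,
and the FDR-thresholded correlation network.

Every randomized stage draws from a child of one seed sequence, so the
whole run is a pure function of (inputs, config, seed) and stages are
individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .consensus import ConsensusSubtyper, impute_missing
from .io import (
    AbundanceMatrix,
    apply_quantification_limit,
    collapse_peptides_to_proteins,
    load_abundance_matrix,
    load_annotations,
    write_abundance_matrix,
)
from .network import bh_adjust, build_network, correlation_matrix, fisher_exact_2x2, volcano_screen
from .screening import screen_cohort1
from .survival import cox_fit, km_estimate, logrank_test, median_split

logger = logging.getLogger("evsubtype")

__all__ = ["RunReport", "run_pipeline"]


@dataclasses.dataclass
class RunReport:
    """Machine-readable summary of a pipeline run."""

    summary: dict

    def to_json(self) -> str:
        return json.dumps(self.summary, indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _stage_seed(ss: np.random.SeedSequence, index: int) -> int:
    return int(ss.spawn(index + 1)[index].generate_state(1)[0] % (2**31 - 1))


def _stage_indicators(groups: pd.Series) -> pd.DataFrame:
    """Ordinal stage dummies with Stage I as reference."""
    out = {}
    for stage in ("StageII", "StageIII", "StageIV"):
        if (groups == stage).any():
            out[stage.lower()] = (groups == stage).astype(float)
    return pd.DataFrame(out, index=groups.index)


def run_pipeline(
    config: PipelineConfig,
    abundance: str | Path | AbundanceMatrix,
    annotations: str | Path | pd.DataFrame,
    outdir: str | Path,
    level: str = "protein",
    peptide_map: dict | None = None,
) -> RunReport:
    """Execute screen -> impute -> cluster -> survival -> volcano -> network.

    Writes result tables and a JSON summary under ``outdir``; the summary
    is byte-identical across reruns with the same inputs, config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    screen_seed, consensus_seed = _stage_seed(ss, 0), _stage_seed(ss, 1)

    if not isinstance(abundance, AbundanceMatrix):
        abundance = load_abundance_matrix(abundance, level=level, feature_to_protein=peptide_map)
    if not isinstance(annotations, pd.DataFrame):
        annotations = load_annotations(annotations)
    summary: dict = {"config": config.to_dict()}

    # ---- quantification limit -------------------------------------------
    matrix, n_censored = apply_quantification_limit(abundance, config.quantification_limit)
    summary["n_censored_below_limit"] = n_censored
    logger.info("censored %d cells below the quantification limit", n_censored)

    # ---- stage 1: screening ---------------------------------------------
    c1_ids = annotations.loc[annotations["cohort"] == "cohort1", "sample_id"].tolist()
    c1_ids = [s for s in c1_ids if s in matrix.sample_ids]
    screen_groups = set(
        annotations.loc[annotations["sample_id"].isin(c1_ids), "group"]
    )
    candidate_proteins: list[str] | None = None
    if {"StageI", "StageIV", "HC1", "HC2"} <= screen_groups:
        c1 = matrix.subset_samples(c1_ids)
        keep = ~c1.data.isna().all(axis=1)
        c1 = c1.subset_features(c1.data.index[keep])
        screen = screen_cohort1(
            c1,
            annotations,
            alpha=config.screen_alpha,
            top_n=config.rf_top_n,
            n_trees=config.rf_n_trees,
            seed=screen_seed,
        )
        screen.candidates.to_tsv(outdir / "candidates.tsv")
        screen.mds_patients.to_csv(outdir / "mds_patients.tsv", sep="\t")
        screen.mds_all.to_csv(outdir / "mds_all.tsv", sep="\t")
        candidate_proteins = screen.candidates.selected_proteins
        summary["screen"] = {
            "n_features": int(len(screen.candidates.table)),
            "n_selected_features": screen.candidates.n_selected_features,
            "n_selected_proteins": screen.candidates.n_selected_proteins,
        }
        logger.info(
            "screen selected %d features / %d proteins",
            screen.candidates.n_selected_features,
            screen.candidates.n_selected_proteins,
        )
    else:
        logger.info("cohort-1 screening skipped (required groups absent)")

    # ---- stage 2: patient cohort ----------------------------------------
    if matrix.level == "peptide":
        matrix = collapse_peptides_to_proteins(matrix)
    pat = annotations.loc[
        (annotations["cohort"] == "cohort2") & annotations["eligible"].fillna(False)
    ]
    pat = pat.loc[pat["sample_id"].isin(matrix.sample_ids)]
    if len(pat) == 0:
        raise ValueError("zero eligible cohort-2 samples")
    summary["n_eligible_patients"] = int(len(pat))
    m2 = matrix.subset_samples(pat["sample_id"].tolist())
    if candidate_proteins:
        keep_feats = [f for f in m2.feature_ids if f in set(candidate_proteins)]
        m2 = m2.subset_features(keep_feats)
    all_missing = m2.data.isna().all(axis=1)
    summary["n_features_dropped_unquantified"] = int(all_missing.sum())
    m2 = m2.subset_features(m2.data.index[~all_missing])
    fully_quantified = set(m2.data.index[~m2.data.isna().any(axis=1)])

    model = ConsensusSubtyper(
        m2,
        k_range=config.k_range,
        n_resamples=config.n_resamples,
        subsample_fraction=config.subsample_fraction,
        inner=config.inner_clusterer,
        pac_bounds=config.pac_bounds,
        imputation=config.imputation_method,
    )
    run = model.fit(seed=consensus_seed)
    run.write_tables(outdir)
    summary["consensus"] = {
        "chosen_k": run.chosen_k,
        "pac": {str(k): run.pac_values[k] for k in run.k_range},
        "cluster_sizes": {str(c): n for c, n in run.cluster_sizes().items()},
    }
    logger.info("consensus clustering chose k=%d", run.chosen_k)

    m2_imputed = impute_missing(m2, config.imputation_method)

    # compare the two major clusters (all of them when k = 2)
    top2 = sorted(run.cluster_sizes(), key=lambda c: -run.cluster_sizes()[c])[:2]
    in_top2 = run.labels[run.labels.isin(top2)]
    surv = pat.set_index("sample_id").loc[in_top2.index]
    times = surv["os_time"].to_numpy(float)
    events = surv["os_event"].to_numpy(float)
    stat, p_lr = logrank_test(times, events, in_top2.to_numpy())
    summary["survival"] = {
        "logrank_statistic": None if np.isnan(stat) else stat,
        "logrank_p": None if np.isnan(p_lr) else p_lr,
    }
    km_rows = []
    for c in top2:
        ids = in_top2.index[in_top2 == c]
        curve = km_estimate(
            surv.loc[ids, "os_time"].to_numpy(float),
            surv.loc[ids, "os_event"].to_numpy(float),
        )
        frame = curve.to_frame()
        frame.insert(0, "cluster", c)
        km_rows.append(frame)
    pd.concat(km_rows).to_csv(outdir / "km_clusters.tsv", sep="\t", index=False)

    # ---- volcano ---------------------------------------------------------
    # orient the comparison so the poor-prognosis cluster is the numerator:
    # "up" proteins are those elevated where survival is worse
    event_rate = {
        c: float(events[(in_top2 == c).to_numpy()].mean()) for c in top2
    }
    worse_first = sorted(top2, key=lambda c: (-event_rate[c], c))
    summary["poor_prognosis_cluster"] = worse_first[0]
    oriented = in_top2.map({worse_first[0]: 1, worse_first[1]: 2})
    volcano = volcano_screen(
        m2_imputed.subset_samples(list(in_top2.index)),
        oriented,
        fc_threshold=config.volcano_fc_threshold,
        alpha=config.volcano_alpha,
    )
    volcano.table.to_csv(outdir / "volcano.tsv", sep="\t", na_rep="NA")
    summary["volcano"] = {"n_up": len(volcano.up), "n_down": len(volcano.down)}
    logger.info("volcano: %d up, %d down", len(volcano.up), len(volcano.down))

    # ---- median-split survival for fully quantified up-proteins ---------
    focus_proteins = sorted(set(volcano.up) & fully_quantified)
    summary["fully_quantified_up_proteins"] = focus_proteins
    median_split_p: dict[str, float | None] = {}
    for prot in focus_proteins:
        split = median_split(m2_imputed.data.loc[prot, surv.index].to_numpy())
        _, p = logrank_test(times, events, split)
        median_split_p[prot] = None if np.isnan(p) else p
    summary["median_split_logrank_p"] = median_split_p

    # ---- Cox multivariate -----------------------------------------------
    cov = pd.DataFrame(index=surv.index)
    cov["age"] = surv["age"].astype(float)
    cov["sex_male"] = (surv["sex"] == "M").astype(float)
    cov = pd.concat([cov, _stage_indicators(surv["group"])], axis=1)
    for prot in focus_proteins:
        cov[f"log2_{prot}"] = np.log2(m2_imputed.data.loc[prot, surv.index].to_numpy())
    cox_scopes = {"all_patients": surv.index}
    if config.stage_iv_only:
        cox_scopes["stage_iv"] = surv.index[surv["group"] == "StageIV"]
    summary["cox"] = {}
    for scope, ids in cox_scopes.items():
        sub_cov = cov.loc[ids]
        sub_cov = sub_cov.loc[:, sub_cov.nunique() > 1]
        try:
            fit = cox_fit(
                sub_cov,
                surv.loc[ids, "os_time"].to_numpy(float),
                surv.loc[ids, "os_event"].to_numpy(float),
            )
        except ValueError as exc:
            summary["cox"][scope] = {"error": str(exc)}
            logger.warning("Cox fit (%s) failed: %s", scope, exc)
            continue
        fit.table.to_csv(outdir / f"cox_{scope}.tsv", sep="\t")
        summary["cox"][scope] = {
            cov_name: {"coef": row["coef"], "hazard_ratio": row["hazard_ratio"], "p": row["p"]}
            for cov_name, row in fit.table.iterrows()
        }

    # ---- curative resection vs cluster (stage IV) ------------------------
    s4 = surv.loc[(surv["group"] == "StageIV") & surv["curative_resection"].notna()]
    if len(s4) and in_top2.loc[s4.index].nunique() == 2:
        lab4 = in_top2.loc[s4.index]
        table = [
            [
                int(((lab4 == c) & (s4["curative_resection"] == status)).sum())
                for status in ("yes", "no")
            ]
            for c in top2
        ]
        summary["curative_resection_fisher_p"] = fisher_exact_2x2(table)
        summary["curative_resection_table"] = table

    # ---- correlation network --------------------------------------------
    pairs = correlation_matrix(m2_imputed, method=config.correlation_method)
    pairs["q"] = bh_adjust(pairs["p"].to_numpy())
    pairs.to_csv(outdir / "correlations.tsv", sep="\t", index=False, na_rep="NA")
    net = build_network(
        pairs,
        q_threshold=config.network_fdr_threshold,
        positive_only=config.positive_only,
        focus=volcano.up or None,
    )
    net.edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    n_sig = int((pairs["q"] < config.network_fdr_threshold).fillna(False).sum())
    summary["network"] = {
        "n_significant_pairs": n_sig,
        "n_edges": int(len(net.edges)),
        "n_nodes": len(net.nodes),
        "isolated_focus": net.isolated_focus,
    }

    write_abundance_matrix(m2_imputed, outdir / "cohort2_imputed.tsv")
    report = RunReport(summary=summary)
    report.write(outdir / "summary.json")
    return report
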