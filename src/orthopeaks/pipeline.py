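"""End-to-end orchestration: simulate -> conserve -> cooccupy -> quantify
-> enrich -> model -> report.

Every stage reads its inputs from files under the run directory and
writes its outputs back there, so stages can be re-run individually; each
stage derives its own random generator from the run seed and the stage
name, making re-runs (full or partial) reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chain_lift, cooccupancy, enrichment_stats, expression_model
from . import genome_model as gm
from . import peak_conservation as pc
from . import signal_quant, synthetic_data

log = logging.getLogger(__name__)

STAGES = ("simulate", "conserve", "cooccupy", "quantify", "enrich", "model", "report")

DEFAULT_CONFIG = {
    "seed": 7,
    "outdir": "orthopeaks_run",
    "simulate": {},                      # SyntheticConfig overrides
    "lift": {"min_match": 0.10, "flank": 50},
    "conserve": {"comp_window": 5000, "strong_fraction": 0.10},
    "cooccupy": {
        "radius": 1000,
        "panel": ["GATA1", "TAL1", "KLF1"],
        "max_gene_distance": 50000,
    },
    "quantify": {
        "bin_width": 25,
        "fragment_length": 200,
        "upstream": 2000,
        "downstream": 2000,
    },
    "enrich": {"n_perm": 100000},
    "model": {"n_folds": 10, "one_se": True, "stage": "ProE", "specific_fraction": 0.10},
    "categories": {"proximity_window": 10000},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = json.load(fh)
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _stage_rng(cfg: dict, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg["seed"]), STAGES.index(stage)])


def _sim_dir(cfg: dict) -> Path:
    return Path(cfg["outdir"]) / "sim"


def _read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict) -> None:
    sim_cfg = synthetic_data.config_from_dict(cfg.get("simulate"))
    dataset, rng = synthetic_data.generate_all(sim_cfg, int(cfg["seed"]))
    outdir = _sim_dir(cfg)
    dataset.write(outdir, write_tags=True, rng=rng)
    # planted combinatorial CRM peak files for the co-occupancy stage
    for species, by_tf in (
        ("mouse", dataset.regions.src_peaks_by_tf),
        ("human", dataset.regions.dst_peaks_by_tf),
    ):
        for tf, peaks in by_tf.items():
            gm.write_peaks(outdir / f"crm_{species}_{tf}.narrowPeak", peaks)


def _tf_names(cfg: dict) -> list[str]:
    sim = _sim_dir(cfg)
    names = sorted(
        p.name[len("peaks_mouse_"):-len(".narrowPeak")]
        for p in sim.glob("peaks_mouse_*.narrowPeak")
    )
    if not names:
        raise FileNotFoundError(f"no peak files under {sim}; run the simulate stage")
    return names


def stage_conserve(cfg: dict) -> None:
    out = Path(cfg["outdir"])
    sim = _sim_dir(cfg)
    chains = chain_lift.read_chain(sim / "alignment.chain")
    index = chain_lift.ChainIndex(chains)
    lift_cfg = cfg["lift"]
    con_cfg = cfg["conserve"]
    summaries = {}
    for tf in _tf_names(cfg):
        src = gm.read_peaks(sim / f"peaks_mouse_{tf}.narrowPeak")
        dst = gm.read_peaks(sim / f"peaks_human_{tf}.narrowPeak")
        cls = pc.classify_source_peaks(
            src, dst, index,
            flank=lift_cfg["flank"],
            comp_window=con_cfg["comp_window"],
            min_match=lift_cfg["min_match"],
        )
        dst_labels = pc.classify_target_peaks(
            dst, cls.conserved_dst, cls.compensatory_dst,
            strong_fraction=con_cfg["strong_fraction"],
        )
        summaries[tf] = cls.summary.to_dict()
        rows = [
            {
                "chrom": p.chrom, "start": p.interval.start, "end": p.interval.end,
                "summit": p.summit, "score": p.score, "label": lab,
            }
            for p, lab in zip(dst, dst_labels)
        ]
        pd.DataFrame(rows).to_csv(out / f"conservation_human_{tf}.tsv", sep="\t", index=False)
        rows = [
            {
                "chrom": p.chrom, "start": p.interval.start, "end": p.interval.end,
                "summit": p.summit, "score": p.score, "label": lab,
                "lifted_chrom": iv.chrom if iv else ".",
                "lifted_start": iv.start if iv else -1,
                "lifted_end": iv.end if iv else -1,
            }
            for p, lab, iv in zip(src, cls.labels, cls.lifted)
        ]
        pd.DataFrame(rows).to_csv(out / f"conservation_mouse_{tf}.tsv", sep="\t", index=False)
    _write_json(out / "conservation_summary.json", summaries)


def stage_cooccupy(cfg: dict) -> None:
    out = Path(cfg["outdir"])
    sim = _sim_dir(cfg)
    co_cfg = cfg["cooccupy"]
    panel = co_cfg["panel"]
    chains = chain_lift.read_chain(sim / "alignment.chain")
    index = chain_lift.ChainIndex(chains)

    def peaks_for(species: str) -> dict:
        by_tf = {}
        for tf in panel:
            path = sim / f"crm_{species}_{tf}.narrowPeak"
            if not path.exists():
                path = sim / f"peaks_{species}_{tf}.narrowPeak"
            by_tf[tf] = gm.read_peaks(path)
        return by_tf

    src_regions = cooccupancy.build_regions(peaks_for("mouse"), radius=co_cfg["radius"])
    dst_regions = cooccupancy.build_regions(peaks_for("human"), radius=co_cfg["radius"])
    tm = cooccupancy.transfer_regions(
        src_regions, dst_regions, index,
        flank=cfg["lift"]["flank"], min_match=cfg["lift"]["min_match"],
    )
    tm.counts.to_csv(out / "cooccupancy_counts.tsv", sep="\t")
    tm.proportions.to_csv(out / "cooccupancy_proportions.tsv", sep="\t")

    # conserved CRMs: full-panel source regions mapping onto full-panel
    # destination regions
    full = cooccupancy.group_label(panel)
    conserved_crms = []
    dst_by_chrom: dict[str, list] = {}
    for r in dst_regions:
        dst_by_chrom.setdefault(r.interval.chrom, []).append(r)
    for region in src_regions:
        if region.label != full:
            continue
        res = chain_lift.lift_interval(
            cooccupancy._representative_window(region, cfg["lift"]["flank"], 500),
            index, min_match=cfg["lift"]["min_match"],
        )
        if not res.is_mapped:
            continue
        iv = res.mapped_interval
        for cand in dst_by_chrom.get(iv.chrom, ()):
            if cand.label == full and cand.interval.overlap_length(iv) > 0:
                conserved_crms.append(cand)
                break
    genes_dst = gm.read_gene_table(sim / "genes_human.tsv")
    assigned = cooccupancy.assign_regions_to_genes(
        conserved_crms, genes_dst, max_distance=co_cfg["max_gene_distance"]
    )
    rows = [
        {
            "chrom": r.interval.chrom, "start": r.interval.start,
            "end": r.interval.end, "tf_set": r.label, "gene_id": g or ".",
        }
        for r, g in zip(conserved_crms, assigned)
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "tf_set", "gene_id"]).to_csv(
        out / "conserved_crms.tsv", sep="\t", index=False
    )


def stage_quantify(cfg: dict) -> None:
    out = Path(cfg["outdir"])
    sim = _sim_dir(cfg)
    q = cfg["quantify"]
    chrom_sizes = _read_json(sim / "chrom_sizes.json")
    for species in ("mouse", "human"):
        genes = gm.read_gene_table(sim / f"genes_{species}.tsv")
        sizes = chrom_sizes[species]
        input_df = _read_tag_frame(sim / f"input_{species}.bed")
        input_track = signal_quant.pileup_tag_frame(
            input_df, sizes, q["fragment_length"], q["bin_width"]
        )
        tracks = {}
        mark_files = sorted(sim.glob(f"tags_{species}_*.bed"))
        for path in mark_files:
            mark = path.name[len(f"tags_{species}_"):-len(".bed")]
            df = _read_tag_frame(path)
            raw = signal_quant.pileup_tag_frame(
                df, sizes, q["fragment_length"], q["bin_width"]
            )
            tracks[mark] = signal_quant.normalize_subtract(
                raw, input_track, raw.n_tags, input_track.n_tags
            )
        pm = signal_quant.promoter_matrix(
            tracks, genes, upstream=q["upstream"], downstream=q["downstream"]
        )
        pm.to_csv(out / f"promoter_matrix_{species}.tsv", sep="\t")
        if {"H3K4me3", "H3K27me3"} <= set(pm.columns):
            signal_quant.promoter_mark_class(pm).to_csv(
                out / f"promoter_class_{species}.tsv", sep="\t"
            )
        corr = pm.corr(method="pearson")
        corr.to_csv(out / f"promoter_correlation_{species}.tsv", sep="\t")
        if "H3K4me3" in tracks:
            profile = signal_quant.metagene_profile(
                tracks["H3K4me3"], genes, flank=2000, body_bins=100
            )
            pd.DataFrame({"bin": range(len(profile)), "signal": profile}).to_csv(
                out / f"metagene_H3K4me3_{species}.tsv", sep="\t", index=False
            )


def _read_tag_frame(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        usecols=[0, 1, 2, 5],
    )
    return df


def _labeled_intervals(cfg: dict) -> dict[str, list[gm.GenomeInterval]]:
    """Category -> destination-genome intervals from the conserve stage."""
    out = Path(cfg["outdir"])
    by_label: dict[str, list[gm.GenomeInterval]] = {
        "conserved": [], "compensatory": [], "gained": [],
        "strongly_gained": [], "lost": [],
    }
    for tf in _tf_names(cfg):
        dst = pd.read_csv(out / f"conservation_human_{tf}.tsv", sep="\t")
        for row in dst.itertuples(index=False):
            by_label[row.label].append(gm.GenomeInterval(row.chrom, row.start, row.end))
        src = pd.read_csv(out / f"conservation_mouse_{tf}.tsv", sep="\t")
        lost = src[(src.label == "lost")]
        for row in lost.itertuples(index=False):
            by_label["lost"].append(
                gm.GenomeInterval(row.lifted_chrom, row.lifted_start, row.lifted_end)
            )
    return by_label


def stage_enrich(cfg: dict) -> None:
    out = Path(cfg["outdir"])
    sim = _sim_dir(cfg)
    rng = _stage_rng(cfg, "enrich")
    chrom_sizes = _read_json(sim / "chrom_sizes.json")["human"]
    workspace = [gm.GenomeInterval(c, 0, n) for c, n in sorted(chrom_sizes.items())]

    # permutation association of conserved CRMs with TF occupancy
    crms = pd.read_csv(out / "conserved_crms.tsv", sep="\t")
    query = [
        gm.GenomeInterval(r.chrom, r.start, r.end) for r in crms.itertuples(index=False)
    ]
    enrichment = {}
    if query:
        panel = cfg["cooccupy"]["panel"]
        ref_tf = panel[-1]
        ref_path = sim / f"crm_human_{ref_tf}.narrowPeak"
        if not ref_path.exists():
            ref_path = sim / f"peaks_human_{ref_tf}.narrowPeak"
        reference = [p.interval for p in gm.read_peaks(ref_path)]
        res = enrichment_stats.permutation_enrichment(
            query, reference, workspace,
            n_perm=int(cfg["enrich"]["n_perm"]),
            seed=rng,
        )
        enrichment[f"conserved_crms_vs_{ref_tf}"] = res.to_dict()
    _write_json(out / "enrichment.json", enrichment)

    # chromatin-state folds per conservation category
    segments = gm.read_segmentation(sim / "segmentation_human.bed")
    by_label = _labeled_intervals(cfg)
    rows = []
    per_site_active: dict[str, list[float]] = {}
    active_state = None
    state_rows = []
    for label, ivs in by_label.items():
        if not ivs:
            continue
        se = enrichment_stats.state_overlap_enrichment(segments, ivs, workspace)
        for state, fold in sorted(se.folds.items()):
            state_rows.append(
                {
                    "category": label, "state": state, "fold": fold,
                    "query_fraction": se.query_fraction[state],
                    "workspace_fraction": se.workspace_fraction[state],
                }
            )
    pd.DataFrame(state_rows).to_csv(out / "state_enrichment.tsv", sep="\t", index=False)

    # rank-sum comparison of per-site active-state coverage, conserved vs lost
    seg_active = gm.merge_intervals(
        s.interval for s in segments if s.state == _dominant_active_state(state_rows)
    )
    lookup: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for iv in seg_active:
        lookup.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, spans in list(lookup.items()):
        starts = np.array([s for s, _ in spans])
        ends = np.array([e for _, e in spans])
        cum = np.concatenate([[0], np.cumsum(ends - starts)])
        lookup[chrom] = (starts, ends, cum)

    def covered_below(chrom: str, x: int) -> int:
        if chrom not in lookup:
            return 0
        starts, ends, cum = lookup[chrom]
        j = int(np.searchsorted(starts, x, side="right")) - 1
        if j < 0:
            return 0
        return int(cum[j]) + max(0, min(x, int(ends[j])) - int(starts[j]))

    pvals = {}
    fractions = {}
    for label in ("conserved", "strongly_gained", "compensatory", "gained", "lost"):
        ivs = by_label.get(label) or []
        fr = [
            (covered_below(iv.chrom, iv.end) - covered_below(iv.chrom, iv.start))
            / iv.length
            for iv in ivs
        ]
        fractions[label] = fr
    for label in ("conserved", "strongly_gained", "compensatory", "gained"):
        if fractions[label] and fractions["lost"]:
            pvals[f"{label}_vs_lost"] = enrichment_stats.rank_sum_compare(
                fractions[label], fractions["lost"]
            )
    _write_json(out / "state_ranksum.json", pvals)


def _dominant_active_state(state_rows: list[dict]) -> int:
    """State with the highest fold at conserved sites (the analysis's
    'active' state)."""
    best, best_fold = 1, -np.inf
    for row in state_rows:
        if row["category"] == "conserved" and row["state"] != 0 and row["fold"] > best_fold:
            best, best_fold = row["state"], row["fold"]
    return best


def stage_model(cfg: dict) -> None:
    out = Path(cfg["outdir"])
    sim = _sim_dir(cfg)
    m = cfg["model"]
    rng = _stage_rng(cfg, "model")
    genes_src = gm.read_gene_table(sim / "genes_mouse.tsv")
    genes_dst = gm.read_gene_table(sim / "genes_human.tsv")
    pairs = [(g.gene_id, g.ortholog_id) for g in genes_src if g.ortholog_id]

    pm_m = pd.read_csv(out / "promoter_matrix_mouse.tsv", sep="\t", index_col=0)
    pm_h = pd.read_csv(out / "promoter_matrix_human.tsv", sep="\t", index_col=0)
    expr_m = gm.read_expression(sim / "expression_mouse.tsv")
    expr_h = gm.read_expression(sim / "expression_human.tsv")

    paired = [(a, b) for a, b in pairs if a in pm_m.index and b in pm_h.index]
    ids_m = [a for a, _ in paired]
    ids_h = [b for _, b in paired]
    Xm = pm_m.loc[ids_m].reset_index(drop=True)
    Xh = pm_h.loc[ids_h].reset_index(drop=True)
    Xh_n, Xm_n = expression_model.quantile_normalize([Xh, Xm])
    Xh_n.index = pd.Index(ids_h)
    Xm_n.index = pd.Index(ids_h)  # align difference rows on human ids

    stage_name = m["stage"]
    yh = expression_model.log_fpkm_response(expr_h, stage_name).reindex(ids_h)
    ym_raw = expression_model.log_fpkm_response(expr_m, stage_name)
    ym = pd.Series(
        [ym_raw.get(a, np.nan) for a in ids_m], index=pd.Index(ids_h)
    )
    keep = yh.notna() & ym.notna()
    Xh_n, Xm_n, yh, ym = Xh_n[keep], Xm_n[keep], yh[keep], ym[keep]

    fit = expression_model.fit_consensus(
        Xh_n, yh.to_numpy(), Xm_n, ym.to_numpy(),
        n_folds=int(m["n_folds"]), one_se=bool(m["one_se"]), seed=rng,
    )
    sets = expression_model.define_species_specific_genes(
        expr_h, expr_m, [(b, a) for a, b in paired],
        stage=stage_name, fraction=float(m["specific_fraction"]),
    )
    subset = set(sets.human_specific) | set(sets.mouse_specific)
    diff = expression_model.predict_difference(
        fit.model, Xh_n, Xm_n, yh, ym, subset=subset
    )

    by_label = _labeled_intervals(cfg)
    categories = pc.assign_gene_categories(
        genes_dst, by_label, window=int(cfg["categories"]["proximity_window"])
    )
    expr_cat = expression_model.expression_by_category(expr_h, categories)
    expr_cat.to_csv(out / "expression_by_category.tsv", sep="\t", index=False)
    diff_cat = expression_model.expression_difference_by_category(
        expr_h, expr_m, [(b, a) for a, b in paired], categories
    )
    diff_cat.to_csv(out / "expression_difference_by_category.tsv", sep="\t", index=False)
    corr = expression_model.expression_correlation(
        {"human": expr_h, "mouse": expr_m}, pairs=[(b, a) for a, b in paired]
    )
    corr.to_csv(out / "expression_correlation.tsv", sep="\t")

    # species-specific gene odds per occupancy category
    odds = {}
    special = set(sets.human_specific)
    rest = set(sets.rest)
    for label, ivs in by_label.items():
        if not ivs:
            continue
        occupied = {
            g for g, cat in categories.items() if cat == label
        }
        try:
            lor, pval = enrichment_stats.category_gene_odds(special, rest, occupied)
            odds[label] = {"log2_odds_ratio": lor, "fisher_p": pval}
        except ValueError:
            continue
    _write_json(out / "gene_odds.json", odds)

    model_summary = {
        "consensus": fit.model.to_dict(),
        "r2_per_species": fit.r2_per_species,
        "difference_r2_all": diff.r_squared_all,
        "difference_r2_species_specific": diff.r_squared_subset,
        "species_gene_sets": sets.to_dict(),
        "n_paired_genes": int(keep.sum()),
    }
    _write_json(out / "model.json", model_summary)
    pd.DataFrame(
        {
            "gene_id": yh.index,
            "delta_observed": diff.delta_obs,
            "delta_predicted": diff.delta_pred,
        }
    ).to_csv(out / "difference_predictions.tsv", sep="\t", index=False)


SUMMARY_REQUIRED_KEYS = (
    "parameters",
    "conservation",
    "cooccupancy",
    "n_conserved_crms",
    "enrichment",
    "state_enrichment",
    "model",
    "gene_odds",
)


def stage_report(cfg: dict) -> dict:
    out = Path(cfg["outdir"])
    summary = {
        "parameters": {k: cfg[k] for k in cfg if k != "outdir"},
        "conservation": _read_json(out / "conservation_summary.json"),
        "cooccupancy": pd.read_csv(
            out / "cooccupancy_proportions.tsv", sep="\t", index_col=0
        ).to_dict(orient="index"),
        "n_conserved_crms": int(
            len(pd.read_csv(out / "conserved_crms.tsv", sep="\t"))
        ),
        "enrichment": _read_json(out / "enrichment.json"),
        "state_enrichment": pd.read_csv(out / "state_enrichment.tsv", sep="\t").to_dict(
            orient="records"
        ),
        "state_ranksum": _read_json(out / "state_ranksum.json"),
        "model": _read_json(out / "model.json"),
        "gene_odds": _read_json(out / "gene_odds.json"),
    }
    validate_summary(summary)
    _write_json(out / "summary.json", summary)
    return summary


def validate_summary(summary: dict) -> None:
    """Minimal schema check of the report bundle."""
    missing = [k for k in SUMMARY_REQUIRED_KEYS if k not in summary]
    if missing:
        raise ValueError(f"summary missing keys: {missing}")
    for tf, s in summary["conservation"].items():
        if not (0 <= s["rate_conserved"] <= 1):
            raise ValueError(f"conservation rate out of range for {tf}")
    model = summary["model"]
    if model["consensus"]["r_squared"] > 1:
        raise ValueError("R^2 exceeds 1")


def run_pipeline(config, stages: Sequence[str] | None = None) -> dict:
    """Run the pipeline (or a subset of stages); returns the summary dict.

    Stage failures raise with the failing stage named; outputs of
    completed stages stay on disk.
    """
    cfg = load_config(config)
    os.makedirs(cfg["outdir"], exist_ok=True)
    todo = list(stages) if stages else list(STAGES)
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    summary: dict = {}
    funcs = {
        "simulate": stage_simulate,
        "conserve": stage_conserve,
        "cooccupy": stage_cooccupy,
        "quantify": stage_quantify,
        "enrich": stage_enrich,
        "model": stage_model,
        "report": stage_report,
    }
    for stage in STAGES:
        if stage not in todo:
            continue
        log.info("running stage %s", stage)
        try:
            result = funcs[stage](cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        if stage == "report":
            summary = result
    return summary
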