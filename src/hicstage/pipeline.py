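"""End-to-end two-stage pipeline orchestration.

Runs bin -> balance -> quantile-normalize -> compartments -> TADs -> PEIs
-> integration for each stage, then the cross-stage comparisons, writing
deterministic tabular outputs plus a manifest (config hash, seed, row
counts). Inputs are either read-pair files or a simulated stage pair with
planted truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import compartments as comp_mod
from . import contacts, integration, io, normalization, pei as pei_mod
from . import synthetic, tads as tad_mod
from .genome import BinnedGenome

logger = logging.getLogger(__name__)

STAGES = ("bin", "normalize", "compartments", "tads", "pei", "integration")

DEFAULT_CONFIG = {
    "seed": 1,
    "bin_size": 20_000,
    "normalize": {"method": "kr", "ice_tol": 1e-5, "ice_max_iter": 200,
                  "quantile": True},
    "compartments": {"min_abs_delta": None},
    "tad": {
        "di_window": 1_000_000,
        "is_window": 500_000,
        "boundary_score_threshold": 1.5,
        "match_tol_bins": 1,
    },
    "pei": {"fdr": 0.01, "min_distance": 15_000, "max_span": 2_000_000},
    "integration": {"min_abs_log2fc": 1.0},
    "simulate": {
        "n_bins": 400,
        "n_tads": 8,
        "n_peis": 10,
        "frac_a_to_b": 0.10,
        "frac_b_to_a": 0.07,
        "n_genes": 500,
    },
}


def merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (user or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _simulate_inputs(cfg: dict):
    sim = cfg["simulate"]
    seed = int(cfg["seed"])
    truth = synthetic.make_truth(
        n_bins=sim["n_bins"],
        bin_size=cfg["bin_size"],
        n_tads=sim["n_tads"],
        n_peis=sim["n_peis"],
        base_depth=sim.get("base_depth", 800.0),
        plaid_strength=sim.get("plaid_strength", 1.5),
        n_chroms=sim.get("n_chroms", 1),
        seed=seed,
    )
    pair = synthetic.make_stage_pair(
        truth, sim["frac_a_to_b"], sim["frac_b_to_a"], seed=seed + 1
    )
    m_gv = synthetic.simulate_matrix(pair.truth_gv, seed + 2)
    m_mii = synthetic.simulate_matrix(pair.truth_mii, seed + 3)
    expr, genes = synthetic.simulate_stage_expression(
        pair, sim["n_genes"], seed + 4
    )
    gc = synthetic.simulate_gc(pair.truth_gv, seed + 5)
    return pair, {"gv": m_gv, "mii": m_mii}, expr, genes, gc


def _load_inputs(cfg: dict):
    genome = BinnedGenome.from_chrom_sizes_file(
        cfg["chrom_sizes"], cfg["bin_size"]
    )
    matrices = {}
    for stage in ("gv", "mii"):
        pairs = synthetic.read_pairs(cfg["pairs"][stage])
        matrices[stage], _ = contacts.bin_contacts(
            pairs, genome, keep_only_valid=True
        )
    genes = io.read_genes_bed6(cfg["genes"])
    expr = pd.read_csv(cfg["expression"], sep="\t")
    gc = None
    if cfg.get("gc"):
        track = pd.read_csv(cfg["gc"], sep="\t", header=None,
                            names=["chrom", "start", "end", "value"])
        gc = np.full(genome.n_bins, np.nan)
        for _, r in track.iterrows():
            gc[genome.bin_index(r["chrom"], int(r["start"]))] = r["value"]
    return None, matrices, expr, genes, gc


def run_pipeline(config: dict | None, outdir: str | Path) -> dict:
    """Run the full two-stage comparison; returns the manifest dict.

    Re-running with the same config and inputs reproduces byte-identical
    tabular outputs (all randomness is seeded from ``config['seed']``).
    """
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "stages_completed": [],
        "counts": {},
    }
    try:
        if cfg.get("pairs"):
            for stage in ("gv", "mii"):
                p = Path(cfg["pairs"][stage])
                if not p.exists():
                    raise FileNotFoundError(f"pairs file missing: {p}")
            if not Path(cfg["chrom_sizes"]).exists():
                raise FileNotFoundError(
                    f"chrom sizes file missing: {cfg['chrom_sizes']}"
                )
            pair, matrices, expr, genes, gc = _load_inputs(cfg)
        else:
            pair, matrices, expr, genes, gc = _simulate_inputs(cfg)
            pair.truth_gv.to_json(outdir / "truth_gv.json")
            pair.truth_mii.to_json(outdir / "truth_mii.json")
        manifest["stages_completed"].append("bin")
        for stage, m in matrices.items():
            m.write(outdir / f"matrix_raw_{stage}")
            manifest["counts"][f"contacts_{stage}"] = int(m.total())

        balanced = {}
        for stage, m in matrices.items():
            if cfg["normalize"]["method"] == "ice":
                b, bias = normalization.ice_normalize(
                    m, max_iter=cfg["normalize"]["ice_max_iter"],
                    tol=cfg["normalize"]["ice_tol"],
                )
            else:
                b, bias = normalization.kr_normalize(m)
            balanced[stage] = b
            normalization.write_bias(bias, outdir / f"bias_{stage}.tsv")
        if cfg["normalize"].get("quantile", True):
            qn = normalization.quantile_normalize(
                [balanced["gv"], balanced["mii"]]
            )
            balanced = {"gv": qn[0], "mii": qn[1]}
        for stage, m in balanced.items():
            m.write(outdir / f"matrix_balanced_{stage}")
        manifest["stages_completed"].append("normalize")

        profiles = {}
        for stage, m in balanced.items():
            prof = comp_mod.call_compartments(m, gc=gc)
            prof.ab_index = comp_mod.ab_index(m, prof)
            profiles[stage] = prof
            io.write_bedgraph(m.genome, prof.pc1, outdir / f"pc1_{stage}.bedgraph")
            io.write_bedgraph(m.genome, prof.ab_index,
                              outdir / f"ab_index_{stage}.bedgraph")
            manifest["counts"][f"bins_labeled_{stage}"] = int(
                prof.included().sum()
            )
        manifest["stages_completed"].append("compartments")

        tadsets, di_tracks, is_tracks = {}, {}, {}
        for stage, m in balanced.items():
            di = tad_mod.directionality_index(
                m, window_bp=cfg["tad"]["di_window"]
            )
            hmm = tad_mod.fit_hmm(di, seed=int(cfg["seed"]))
            ist = tad_mod.insulation_score(
                m, window_bp=cfg["tad"]["is_window"]
            )
            ts = tad_mod.call_tads(hmm, ist)
            tad_mod.domain_score(m, ts)
            tad_mod.tad_compartment_label(ts, profiles[stage])
            tadsets[stage], di_tracks[stage], is_tracks[stage] = ts, di, ist
            io.write_bedgraph(m.genome, di.values, outdir / f"di_{stage}.bedgraph")
            io.write_bedgraph(m.genome, ist.values, outdir / f"is_{stage}.bedgraph")
            _write_tads_bed(ts, outdir / f"tads_{stage}.bed")
            manifest["counts"][f"tads_{stage}"] = int(len(ts.domains()))
        manifest["stages_completed"].append("tads")

        promoters = pei_mod.make_promoters(genes, balanced["gv"].genome)
        peisets = {}
        for stage, m in balanced.items():
            m_scaled = pei_mod.scale_to_depth(
                m, matrices[stage].total()
            )
            bg = pei_mod.fit_domain_background(m_scaled, tadsets[stage])
            ps = pei_mod.call_peis(
                m_scaled, promoters, bg,
                fdr_threshold=cfg["pei"]["fdr"],
                min_distance=cfg["pei"]["min_distance"],
                max_span=cfg["pei"]["max_span"],
            )
            peisets[stage] = ps
            pei_mod.write_bedpe(ps, outdir / f"peis_{stage}.bedpe")
            manifest["counts"][f"peis_{stage}"] = int(len(ps.table))
        manifest["stages_completed"].append("pei")

        switches = comp_mod.detect_switches(
            profiles["gv"], profiles["mii"],
            min_abs_delta=cfg["compartments"]["min_abs_delta"],
            gene_annotation=genes,
        )
        switches.regions.to_csv(outdir / "switch_regions.tsv", sep="\t",
                                index=False)
        tad_cmp = tad_mod.compare_tads(
            tadsets["gv"], tadsets["mii"],
            di_tracks["gv"], di_tracks["mii"],
            is_tracks["gv"], is_tracks["mii"],
            match_tol_bins=cfg["tad"]["match_tol_bins"],
            boundary_score_threshold=cfg["tad"]["boundary_score_threshold"],
        )
        tad_cmp.boundary_scores.to_csv(outdir / "boundary_scores.tsv",
                                       sep="\t", index=False)
        delta, losers, gainers = pei_mod.compare_pei_sets(
            peisets["gv"], peisets["mii"]
        )
        delta.to_csv(outdir / "pei_gene_delta.tsv", sep="\t", index=False)

        de = integration.differential_expression_flags(
            expr, min_abs_log2fc=cfg["integration"]["min_abs_log2fc"]
        )
        switch_genes = sorted(
            set(switches.genes_by_class["AB"]) | set(switches.genes_by_class["BA"])
        )
        tad_genes = _genes_in_regions(tad_cmp.differential_tads, genes)
        venn = integration.dynamic_gene_overlap(
            switch_genes, tad_genes, expr.loc[de, "gene"].tolist()
        )
        with open(outdir / "venn.json", "w") as fh:
            json.dump(
                {
                    "only_switch": venn.only_switch,
                    "only_tad": venn.only_tad,
                    "only_de": venn.only_de,
                    "switch_tad": venn.switch_tad,
                    "switch_de": venn.switch_de,
                    "tad_de": venn.tad_de,
                    "triple": venn.triple,
                    "triple_genes": venn.triple_genes,
                },
                fh, indent=1, sort_keys=True,
            )
        summary = {
            "jaccard": tad_cmp.jaccard,
            "spearman_di": tad_cmp.spearman_di,
            "switch_fractions": switches.fractions,
            "compartment_fractions_gv": profiles["gv"].fractions(),
            "compartment_fractions_mii": profiles["mii"].fractions(),
        }
        with open(outdir / "comparison_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        manifest["stages_completed"].append("integration")
        manifest["counts"]["switch_regions"] = int(len(switches.regions))
        manifest["counts"]["differential_boundaries"] = int(
            len(tad_cmp.differential_boundaries)
        )
    except Exception as err:
        failed = STAGES[len(manifest["stages_completed"])] if len(
            manifest["stages_completed"]
        ) < len(STAGES) else "comparison"
        manifest["failed_stage"] = failed
        (outdir / "manifest.json").write_text(
            json.dumps({**manifest, "valid": False}, indent=1, sort_keys=True)
        )
        raise RuntimeError(f"pipeline failed at stage '{failed}': {err}") from err

    manifest["valid"] = True
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest


def _write_tads_bed(ts, path) -> None:
    with open(path, "w") as fh:
        for _, r in ts.table.iterrows():
            score = 0 if not np.isfinite(r["dscore"]) else int(
                round(1000 * r["dscore"])
            )
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['class']}\t"
                f"{score}\t.\n"
            )


def _genes_in_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> list:
    if len(regions) == 0:
        return []
    out = set()
    for _, r in regions.iterrows():
        hit = genes[
            (genes["chrom"] == r["chrom"])
            & (genes["start"] < r["end"])
            & (genes["end"] > r["start"])
        ]
        out.update(hit["gene"].tolist())
    return sorted(out)
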