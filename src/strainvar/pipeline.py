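"""End-to-end orchestration of the analysis stages on one configuration.

``run_pipeline`` executes simulate -> variance -> fit-simple -> fit-ahr ->
heritability -> cluster -> enrich -> tfbs -> map in order, writing each
stage's table as a TSV whose header block records the package version, the
root seed and the stage parameters.  One root seed drives everything:
per-stage child seeds are derived by stable hashing of the stage name, so
adding or removing a stage never perturbs another stage's randomness, and
re-running the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import logging
import zlib
from pathlib import Path

import pandas as pd
import yaml

import strainvar
from strainvar import clustering, enrichment, genome_map, heritability, synth, tfbs
from strainvar import linear_models as lm
from strainvar import variance as vp
from strainvar.core_io import write_expression_matrix, write_fasta, write_loci

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "stage_seed"]

DEFAULT_STAGES = (
    "simulate",
    "variance",
    "fit_simple",
    "fit_ahr",
    "heritability",
    "cluster",
    "enrich",
    "tfbs",
    "map",
)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2^31."""
    return (int(root_seed) + zlib.crc32(stage.encode())) % (2**31 - 1)


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, params: dict, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# strainvar {strainvar.__version__}\n# seed: {seed}\n")
        for k, v in params.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config, out_dir=None) -> dict:
    """Run the configured stages; returns the in-memory stage results.

    ``config`` is a mapping or a YAML file path with keys ``seed`` (root
    seed), ``outdir``, ``stages`` (subset of the default order), and
    optional per-stage parameter blocks ``simulate``, ``cluster``,
    ``enrich``, ``tfbs``, ``map``.  Stages fail fast, naming themselves,
    when an upstream product they need was not configured.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    known = {"seed", "outdir", "stages", "simulate", "cluster", "enrich", "tfbs", "map"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("outdir", "strainvar_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", DEFAULT_STAGES))
    bad = [s for s in stages if s not in DEFAULT_STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    results: dict = {"seed": seed}

    def need(stage: str, *deps: str) -> None:
        missing = [d for d in deps if d not in results]
        if missing:
            raise RuntimeError(f"stage {stage!r} requires missing stage(s): {missing}")

    if "simulate" in stages:
        params = dict(config.get("simulate", {}))
        sim_cfg = synth.SimulationConfig(seed=stage_seed(seed, "simulate"), **params)
        X, truth = synth.simulate_expression(sim_cfg)
        results["simulate"] = (X, truth)
        write_expression_matrix(X, out / "expression.tsv", out / "samples.tsv")
        _write_tsv(truth.table, out / "truth.tsv", seed, params)
        log.info("simulate: %d genes x %d samples", X.n_genes, len(X.samples))

    if "variance" in stages:
        need("variance", "simulate")
        X, _ = results["simulate"]
        part = vp.partition_variance(X)
        results["variance"] = part
        _write_tsv(part, out / "variance_partition.tsv", seed, {})

    if "fit_simple" in stages:
        need("fit_simple", "simulate")
        X, _ = results["simulate"]
        fit = lm.moderate(lm.fit_genewise(X, lm.build_design(X.samples, "simple")))
        results["fit_simple"] = fit
        table = pd.concat(
            [fit.M.add_prefix("M_"), fit.q.add_prefix("q_"), fit.F_p.rename("F_p")], axis=1
        )
        _write_tsv(table, out / "fit_simple.tsv", seed, {"d0": fit.d0, "s02": fit.s02})
        _write_tsv(lm.threshold_sensitivity(fit), out / "threshold_sensitivity.tsv", seed, {})

    if "fit_ahr" in stages:
        need("fit_ahr", "simulate")
        X, _ = results["simulate"]
        fit = lm.moderate(lm.fit_genewise(X, lm.build_design(X.samples, "ancestry_ahr")))
        results["fit_ahr"] = fit
        table = pd.DataFrame(
            {"A": fit.amean, "M": fit.M["AHR"], "t": fit.t["AHR"],
             "p": fit.p["AHR"], "q": fit.q["AHR"]}
        )
        _write_tsv(table.join(fit.beta), out / "fit_ahr.tsv", seed,
                   {"d0": fit.d0, "s02": fit.s02})

    if "heritability" in stages:
        need("heritability", "simulate", "fit_simple")
        X, _ = results["simulate"]
        profile = heritability.distance_profile(X, results["fit_simple"])
        interacting = heritability.find_interacting_loci(results["fit_simple"])
        results["heritability"] = (profile, interacting)
        _write_tsv(profile.records, out / "heritability_distances.tsv", seed, {})
        _write_tsv(interacting, out / "interacting_loci.tsv", seed, {}, index=False)

    if "cluster" in stages:
        need("cluster", "simulate")
        X, _ = results["simulate"]
        params = dict(config.get("cluster", {}))
        threshold = params.get("variance_threshold", 0.25)
        dend = clustering.cluster_samples(X, threshold=threshold)
        results["cluster"] = dend
        (out / "samples_dendrogram.newick").write_text(dend.to_newick() + "\n")
        k = params.get("k", len(X.strains))
        assign = pd.DataFrame({"sample_id": dend.labels, "cluster": dend.cut(k)})
        _write_tsv(assign, out / "cluster_assignments.tsv", seed,
                   {"k": k, "variance_threshold": threshold}, index=False)

    if "enrich" in stages:
        need("enrich", "simulate", "variance", "fit_simple", "fit_ahr")
        X, _ = results["simulate"]
        params = dict(config.get("enrich", {}))
        ann = synth.simulate_annotations(
            X.gene_ids,
            n_terms=params.get("n_terms", 50),
            genes_per_term=params.get("genes_per_term", max(10, X.n_genes // 50)),
            seed=stage_seed(seed, "enrich"),
        )
        dec = enrichment.decile_enrichment(results["variance"], ann,
                                           min_p=params.get("min_p", 1e-5))
        con = enrichment.contrast_enrichment(results["fit_simple"], results["fit_ahr"], ann)
        kept = enrichment.cumulative_term_selection(con, params.get("cutoff", -10.0))
        results["enrich"] = (dec, con, kept)
        _write_tsv(dec, out / "enrichment_deciles.tsv", seed, params)
        _write_tsv(con, out / "enrichment_contrasts.tsv", seed, params)
        _write_tsv(kept, out / "enrichment_selected.tsv", seed, params)

    if "tfbs" in stages:
        need("tfbs", "simulate", "fit_ahr")
        X, _ = results["simulate"]
        params = dict(config.get("tfbs", {}))
        tf_seed = stage_seed(seed, "tfbs")
        motif = params.get("motif") or _demo_motif()
        ahr_genes = list(lm.ahr_effect_table(results["fit_ahr"]).index)
        if not ahr_genes:
            log.warning("tfbs: no AHR-significant genes; skipping stage")
        else:
            n_bg = min(params.get("n_background", 300), X.n_genes)
            bg_genes = X.gene_ids[:n_bg]
            length = params.get("promoter_length", 2001)
            proms, _ = synth.simulate_promoters(
                sorted(set(bg_genes) | set(ahr_genes)), length, motif,
                planted_fraction=0.0, seed=tf_seed,
            )
            # plant the motif in the AHR-significant promoters
            planted, _ = synth.simulate_promoters(
                ahr_genes, length, motif, planted_fraction=params.get("planted_fraction", 0.5),
                seed=tf_seed + 1,
            )
            proms.update(planted)
            write_fasta(proms, out / "promoters.fa")
            expressed = tfbs.expressed_background(X)
            res = tfbs.five_test_significance(
                motif,
                [proms[g] for g in ahr_genes],
                [proms[g] for g in bg_genes],
                [proms[g] for g in bg_genes if g in set(expressed)],
                n_perm=params.get("n_perm", 200),
                seed=tf_seed,
            )
            results["tfbs"] = res
            row = {"motif_id": res.motif_id, "raw_score": res.raw_score,
                   **{f"p_{t}": res.p_enrich.get(t) for t in tfbs.TEST_NAMES},
                   "n_enriched": res.n_enriched, "call": res.call}
            _write_tsv(pd.DataFrame([row]), out / "tfbs.tsv", seed, params, index=False)

    if "map" in stages:
        need("map", "simulate", "fit_simple")
        X, _ = results["simulate"]
        params = dict(config.get("map", {}))
        loci = synth.simulate_loci(X.gene_ids, seed=stage_seed(seed, "map"))
        write_loci(loci, out / "loci.tsv")
        f_genes = clustering.f_statistic_filter(results["fit_simple"])
        track = genome_map.map_gene_set(f_genes, loci)
        results["map"] = track
        _write_tsv(track, out / "genome_track.tsv", seed, params, index=False)
        if f_genes:
            scan = genome_map.hotspot_scan(
                f_genes, loci, n_perm=params.get("n_perm", 200),
                seed=stage_seed(seed, "map"),
            )
            _write_tsv(scan, out / "hotspots.tsv", seed, params, index=False)

    return results


def _demo_motif():
    """A sharply peaked 12-mer used when no motif is configured."""
    import numpy as np

    from strainvar.core_io import PWM

    consensus = "ACGTTGCAGCAT"
    counts = np.full((4, len(consensus)), 1.0)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 97.0
    return PWM("DEMO1", "demo motif", counts)
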