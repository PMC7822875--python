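"""End-to-end pipeline: data (simulated or read) -> imputation -> heritability
-> scan -> threshold -> intervals -> founder effects -> mediation.

Every run writes its outputs plus a ``provenance.json`` recording package
and library versions, the full configuration, per-stage seeds, and SHA-256
hashes of every output file — enough to reproduce the run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

import hsqtl
from hsqtl import io
from hsqtl.config import RunConfig
from hsqtl.diploffect import diploffect_fit
from hsqtl.heritability import MCMCConfig, estimate_h2
from hsqtl.hmm import forward_backward, dosages_from_probs, snp_dosage
from hsqtl.lmm import EigenK, kinship_from_dosages
from hsqtl.mediation import mediate
from hsqtl.prep import rank_inverse_normal
from hsqtl.scan import bootstrap_threshold, ld_interval, lrt_scan
from hsqtl.simulate import (
    SimConfig,
    TruthRecord,
    simulate_expression,
    simulate_phenotype,
    simulate_population,
    true_dosage,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full chain described by ``cfg``; returns the provenance dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def save(name: str, writer, *args) -> Path:
        path = out / name
        writer(path, *args)
        outputs.append(path)
        return path

    # ---- stage 1: data ----------------------------------------------------
    truth: dict = {}
    expression = annotations = None
    if cfg.simulate is not None:
        sim_cfg = SimConfig(
            n_animals=cfg.simulate.n_animals,
            chromosomes=[tuple(c) for c in cfg.simulate.chromosomes],
            n_founders=cfg.simulate.n_founders,
            n_generations=cfg.simulate.n_generations,
            genotyping_error=cfg.simulate.genotyping_error,
            missing_rate=cfg.simulate.missing_rate,
            seed=cfg.stage_seed("simulate"),
        )
        pop = simulate_population(sim_cfg)
        panel, geno, animals = pop.panel, pop.genotypes, pop.animals
        tdose = true_dosage(pop.mosaics, panel)
        K_true = kinship_from_dosages(tdose, ids=animals)
        qtl_spec = []
        if cfg.simulate.qtl is not None:
            if cfg.simulate.qtl.effects == "snp":
                eff = panel.alleles[:, cfg.simulate.qtl.marker_index].astype(float)
            else:
                eff = np.asarray(cfg.simulate.qtl.effects, dtype=float)
            qtl_spec.append((cfg.simulate.qtl.marker_index, eff, cfg.simulate.qtl.fraction))
        record = TruthRecord(qtl_spec=qtl_spec, h2_target=cfg.simulate.h2)
        rng_ph = np.random.default_rng(cfg.stage_seed("phenotype"))
        y_raw = simulate_phenotype(tdose, K_true.values, record, rng_ph)
        trait = "trait"
        if cfg.simulate.expression_scenario is not None:
            if not qtl_spec:
                raise ValueError("expression scenario requires a simulated QTL")
            esim = simulate_expression(
                qtl_spec[0][0], tdose, panel, K_true.values,
                cfg.simulate.expression_scenario,
                np.random.default_rng(cfg.stage_seed("expression")),
                h2_target=cfg.simulate.h2, qtl_fraction=qtl_spec[0][2],
                founder_contrast=qtl_spec[0][1],
            )
            y_raw = esim.phenotype
            expression = esim.counts
            expression.columns = animals
            annotations = esim.annotations
            truth["mediator"] = esim.truth["mediator"]
        truth.update(
            {
                "h2_target": cfg.simulate.h2,
                "qtl": [
                    {"marker_index": int(m), "effects": e.tolist(), "fraction": f}
                    for m, e, f in qtl_spec
                ],
                "scenario": cfg.simulate.expression_scenario,
            }
        )
        save("panel.tsv", io.write_panel, panel)
        save("genotypes.tsv", io.write_genotypes, geno, animals,
             panel.markers["marker"].tolist())
        save("phenotypes.tsv", io.write_phenotypes,
             pd.DataFrame({"animal": animals, trait: y_raw}))
        save("truth.json", io.write_truth_json, truth)
        if expression is not None:
            save("expression.tsv", io.write_expression, expression)
            save("annotations.tsv", lambda p, df: df.to_csv(p, sep="\t", index=False),
                 annotations)
    else:
        panel = io.read_panel(cfg.inputs.panel)
        geno, animals, marker_ids = io.read_genotypes(cfg.inputs.genotypes)
        if marker_ids != panel.markers["marker"].tolist():
            raise ValueError("genotype marker columns do not match the panel")
        pheno = io.read_phenotypes(cfg.inputs.phenotypes)
        trait = cfg.inputs.trait
        if trait not in pheno.columns:
            raise ValueError(f"trait {trait!r} not in phenotype table")
        pheno = pheno.set_index("animal").loc[animals]
        y_raw = pheno[trait].to_numpy(dtype=float)
        if cfg.inputs.expression is not None:
            expression = io.read_expression(cfg.inputs.expression)
            annotations = pd.read_csv(cfg.inputs.annotations, sep="\t")

    # ---- stage 2: imputation ---------------------------------------------
    logger.info("imputing diplotypes for %d animals x %d markers",
                len(animals), panel.n_markers)
    probs = forward_backward(
        geno, panel, generations=cfg.hmm.generations, epsilon=cfg.hmm.epsilon,
        animals=animals,
    )
    fdose = dosages_from_probs(probs, founders=panel.founders)
    sdose = snp_dosage(fdose, panel)
    K = kinship_from_dosages(fdose.dose, ids=animals)
    save("snp_dosage.tsv", io.write_dosage_matrix, sdose, animals,
         panel.markers["marker"].tolist())
    save("kinship.tsv", io.write_kinship, K.values, animals)

    # ---- stage 3: phenotype prep -----------------------------------------
    y = rank_inverse_normal(y_raw)
    save("phenotypes_transformed.tsv", io.write_phenotypes,
         pd.DataFrame({"animal": animals, trait: y}))

    # ---- stage 4: heritability -------------------------------------------
    eig = EigenK.from_kinship(K)
    h2_post = estimate_h2(
        y, eig,
        MCMCConfig(n_iter=cfg.h2.n_iter, burn_in=cfg.h2.burn_in,
                   seed=cfg.stage_seed("h2")),
    )
    save(
        "heritability.tsv",
        lambda p, df: df.to_csv(p, sep="\t", index=False),
        pd.DataFrame(
            [{"trait": trait, "h2_mode": h2_post.mode, "hpd_low": h2_post.hpd_low,
              "hpd_high": h2_post.hpd_high, "ess": h2_post.ess}]
        ),
    )

    # ---- stage 5-7: scan, threshold, intervals ---------------------------
    scan = lrt_scan(y, sdose, eig, markers=panel.markers,
                    grid_size=cfg.scan.grid_size)
    save("scan.tsv", io.write_scan, scan.table)
    thr = bootstrap_threshold(
        scan.null_fit, sdose, B=cfg.scan.B, alpha=cfg.scan.alpha,
        seed=np.random.default_rng(cfg.stage_seed("threshold")),
        markers=panel.markers, grid_size=cfg.scan.grid_size,
    )
    save("threshold.json", lambda p, d: Path(p).write_text(json.dumps(d, indent=2)),
         {"threshold_logp": thr, "B": cfg.scan.B, "alpha": cfg.scan.alpha})

    peak = scan.peak_index()
    interval = ld_interval(scan, sdose, peak_index=peak, r2_min=cfg.scan.r2_min,
                           trait=trait, threshold=thr)
    save("intervals.tsv", io.write_intervals, [interval])

    # ---- stage 8: founder effects at the peak ----------------------------
    est = diploffect_fit(
        y, probs.probs[:, peak, :], eig,
        n_importance=cfg.effects.n_importance,
        mcmc=MCMCConfig(n_iter=cfg.effects.n_iter, burn_in=cfg.effects.burn_in,
                        seed=cfg.stage_seed("effects")),
        seed=cfg.stage_seed("effects"),
        founders=panel.founders,
    )
    eff = est.founder_effects.copy()
    eff.insert(0, "trait", trait)
    save("founder_effects.tsv", lambda p, df: df.to_csv(p, sep="\t", index=False), eff)
    save(
        "qtl_effect_size.tsv",
        lambda p, df: df.to_csv(p, sep="\t", index=False),
        pd.DataFrame(
            [{"trait": trait, "h2_qtl_mode": est.h2_qtl.mode,
              "h2_qtl_mean": float(est.h2_qtl.samples.mean()),
              "hpd_low": est.h2_qtl.hpd_low, "hpd_high": est.h2_qtl.hpd_high,
              "effective_importance_samples": est.effective_m}]
        ),
    )

    # ---- stage 9: mediation ----------------------------------------------
    if expression is not None and annotations is not None:
        med = mediate(
            y, expression, annotations, interval, sdose[:, peak], eig,
            fdr=cfg.mediation.fdr,
            full_mediation_alpha=cfg.mediation.full_mediation_alpha,
        )
        save("mediation.tsv", lambda p, df: df.to_csv(p, sep="\t", index=False), med)

    # ---- provenance -------------------------------------------------------
    prov = {
        "package": {"name": "hsqtl", "version": hsqtl.__version__},
        "libraries": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": json.loads(cfg.model_dump_json()),
        "seed": cfg.seed,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
    return prov
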