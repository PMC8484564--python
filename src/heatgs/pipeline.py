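"""End-to-end study runs: simulate-or-ingest, QC, model training and
optimization, next-generation selection, annotation-based panel retraining
and QTL mapping, with a reproducible manifest.

A run proceeds through the stages of a genomic-selection breeding cycle:

1. obtain training (e.g. F4) and prediction (F5) generation genotypes plus
   training phenotypes — either simulated or loaded from VCF/TSV;
2. marker QC (summaries, MAF filter) and the hold-out grid over test-set
   size x PEMV call-rate level for each trait;
3. final model fit at the best grid cell; cross-generation marker
   intersection; GEBV prediction and threshold selection of candidates
   against a reference genotype; offspring (F6) validation;
4. variant annotation against gene models, and retraining of the model on
   the gene-body panel vs a size-matched random panel vs the full panel;
5. composite interval mapping with a permutation threshold.

Every stage draws its randomness from a child seed of the master seed, so
a run is bit-reproducible and stages can be re-run independently.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annot, gsopt, qtlmap, rrblup, simpop, variantio
from .impute import impute_matrix

STAGES = ("inputs", "qc", "grid", "fit", "predict", "select", "validate",
          "annotate", "panels", "qtl")


@dataclass
class StudyConfig:
    """Configuration of a full run; see YAML schema in the docs.

    When ``vcf_train`` is unset, data are simulated from ``sim``.
    """

    sim: simpop.SimConfig = field(default_factory=simpop.SimConfig)
    # real-data inputs (all optional; presence switches ingest mode)
    vcf_train: str | None = None
    vcf_next: str | None = None
    pheno_train: str | None = None
    pheno_offspring: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    # protocol
    traits: tuple = ("YP", "SSC")
    tst_sizes: tuple = (15, 20, 25, 30, 35)
    pemv_levels: tuple = (70, 75, 80, 85, 90)
    grid_iters: int = 100
    maf_min: float = 0.05
    updown_bp: int = 5000
    qtl_trait: str = "YP"
    qtl_step_cM: float = 2.0
    qtl_n_perm: int = 100
    qtl_alpha: float = 0.05
    qtl_window_cM: float = 15.0
    qtl_n_marcovar: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_kwargs = raw.pop("sim", {})
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        cfg.sim = simpop.SimConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in sim_kwargs.items()
        })
        return cfg


@dataclass
class RunManifest:
    """Provenance record of a run: config hash, seeds, per-stage counts."""

    config_hash: str
    seed: int
    stage_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        payload = json.dumps(
            {"config": self.config_hash, "seed": self.seed,
             "counts": self.stage_counts, "results": self.results},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def save(self, path) -> None:
        data = asdict(self)
        data["manifest_hash"] = self.content_hash()
        with open(path, "wt") as fh:
            json.dump(data, fh, indent=2, default=str)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _hash_config(cfg: StudyConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()


def _simulate_inputs(cfg: StudyConfig, out: Path):
    sim = cfg.sim
    gens = tuple(sorted(set(sim.generations) | {"F4", "F5", "F6"},
                        key=simpop.GENERATION_ORDER.index))
    sim = simpop.SimConfig(**{**asdict(sim), "generations": gens})
    mats, truth = simpop.simulate_ssd_population(sim)
    pheno_f4 = simpop.simulate_phenotypes(mats["F4"], truth, sim, "F4")
    pheno_f6 = simpop.simulate_phenotypes(mats["F6"], truth, sim, "F6")
    geno_f4 = simpop.apply_gbs_missingness(mats["F4"], sim, salt=4)
    geno_f5 = simpop.apply_gbs_missingness(mats["F5"], sim, salt=5)
    fasta = out / "genome.synthetic.fa"
    gff3 = out / "genes.synthetic.gff3"
    annot.synthetic_reference(mats["F4"], fasta, gff3, updown_bp=cfg.updown_bp,
                              seed=sim.seed)
    # the reference genotype mirrors the founder hybrid: heterozygous everywhere
    ref = variantio.GenotypeMatrix(
        ["REFHYB"], mats["F4"].markers.copy(),
        np.zeros((1, mats["F4"].n_markers)),
    )
    return {"train": geno_f4, "next": geno_f5, "pheno_train": pheno_f4,
            "pheno_offspring": pheno_f6, "reference": ref,
            "gff3": gff3, "fasta": fasta, "truth": truth}


def _load_inputs(cfg: StudyConfig):
    train = variantio.read_vcf(cfg.vcf_train)
    nxt = variantio.read_vcf(cfg.vcf_next) if cfg.vcf_next else None
    pheno = variantio.read_phenotypes(cfg.pheno_train)
    off = variantio.read_phenotypes(cfg.pheno_offspring) if cfg.pheno_offspring else None
    return {"train": train, "next": nxt, "pheno_train": pheno,
            "pheno_offspring": off, "reference": None,
            "gff3": cfg.gff3, "fasta": cfg.fasta, "truth": None}


def run_study(cfg: StudyConfig, out_dir) -> RunManifest:
    """Execute the full pipeline; returns the run manifest.

    Any stage failure raises :class:`StageFailure` carrying the stage name
    and the manifest accumulated so far.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_hash_config(cfg), seed=cfg.seed)
    stage = "inputs"
    try:
        t0 = time.time()
        data = _simulate_inputs(cfg, out) if cfg.vcf_train is None else _load_inputs(cfg)
        train, nxt = data["train"], data["next"]
        pheno = data["pheno_train"]
        variantio.write_vcf(train, out / "train.vcf")
        variantio.write_phenotypes(pheno, out / "pheno_train.tsv")
        manifest.stage_counts[stage] = {
            "train_markers": train.n_markers, "train_lines": train.n_lines,
            "next_markers": getattr(nxt, "n_markers", 0),
        }
        manifest.timings[stage] = round(time.time() - t0, 3)

        stage = "qc"
        t0 = time.time()
        div = variantio.marker_diversity(train)
        div["per_chrom"].to_csv(out / "qc_per_chrom.tsv", sep="\t")
        maf_filtered = variantio.filter_markers(
            train, variantio.FilterConfig(maf_min=cfg.maf_min, pemv_level=0)
        )
        manifest.stage_counts[stage] = {
            "markers_in": train.n_markers,
            "markers_after_maf": maf_filtered.n_markers,
            "tstv_ratio": round(div["tstv"]["ratio"], 4),
        }
        manifest.timings[stage] = round(time.time() - t0, 3)

        stage = "grid"
        t0 = time.time()
        grids = {}
        for trait in cfg.traits:
            gc = gsopt.GridConfig(
                trait=trait, tst_sizes=cfg.tst_sizes, pemv_levels=cfg.pemv_levels,
                n_iter=cfg.grid_iters, maf_min=cfg.maf_min, seed=cfg.seed + 11,
            )
            grids[trait] = gsopt.holdout_grid(train, pheno, gc)
            grids[trait].mean_accuracy.to_csv(out / f"grid_{trait}.tsv", sep="\t")
        manifest.stage_counts[stage] = {
            t: {"best_cell": list(g.best_cell),
                "best_mean_accuracy": round(float(g.mean_accuracy.loc[g.best_cell[0], g.best_cell[1]]), 4),
                "marker_counts": {str(k): v for k, v in g.marker_counts.items()}}
            for t, g in grids.items()
        }
        manifest.results["grid_best"] = {
            t: manifest.stage_counts[stage][t]["best_mean_accuracy"] for t in grids
        }
        manifest.timings[stage] = round(time.time() - t0, 3)

        stage = "fit"
        t0 = time.time()
        models = {}
        panels = {}
        for trait, grid in grids.items():
            _, best_pemv = grid.best_cell
            panel = variantio.filter_markers(
                train, variantio.FilterConfig(maf_min=cfg.maf_min, pemv_level=best_pemv)
            )
            imputed, _ = impute_matrix(panel)
            y = pheno[trait].loc[list(imputed.line_ids)].to_numpy(dtype=float)
            models[trait] = rrblup.fit_matrix(imputed, y)
            panels[trait] = panel
        manifest.stage_counts[stage] = {
            t: {"markers": panels[t].n_markers, "lambda": round(models[t].lambda_, 4),
                "h2": round(models[t].h2_, 4)} for t in models
        }
        manifest.timings[stage] = round(time.time() - t0, 3)

        sel_tables = {}
        common_train = {}
        common_next = {}
        if nxt is not None:
            stage = "predict"
            t0 = time.time()
            preds = {}
            ref_gebv = {}
            for trait, grid in grids.items():
                _, best_pemv = grid.best_cell
                next_panel = variantio.filter_markers(
                    nxt, variantio.FilterConfig(maf_min=cfg.maf_min, pemv_level=best_pemv)
                )
                a, b = gsopt.intersect_markers(panels[trait], next_panel)
                a_imp, _ = impute_matrix(a)
                b_imp, _ = impute_matrix(b)
                common_train[trait], common_next[trait] = a_imp, b_imp
                y = pheno[trait].loc[list(a_imp.line_ids)].to_numpy(dtype=float)
                model = rrblup.fit_matrix(a_imp, y)
                models[trait] = model
                preds[trait] = rrblup.predict_matrix(model, b_imp)
                if data["reference"] is not None:
                    ref_m = data["reference"]
                    keep = ref_m.markers["id"].isin(a_imp.markers["id"]).to_numpy()
                    ref_sub = ref_m.subset_markers(keep)
                    ref_gebv[trait] = float(
                        rrblup.predict_matrix(model, ref_sub).gebv_absolute[0]
                    )
                else:
                    ref_gebv[trait] = float(np.median(preds[trait].gebv_absolute))
                preds[trait].to_frame().to_csv(out / f"gebv_{trait}.tsv", sep="\t", index=False)
            manifest.stage_counts[stage] = {
                t: {"common_markers": common_train[t].n_markers,
                    "reference_gebv": round(ref_gebv[t], 4)} for t in preds
            }
            manifest.timings[stage] = round(time.time() - t0, 3)

            stage = "select"
            t0 = time.time()
            for trait in cfg.traits:
                sel = gsopt.select_candidates(preds[trait], ref_gebv[trait])
                sel_tables[trait] = sel
                sel.to_csv(out / f"selection_{trait}.tsv", sep="\t", index=False)
            manifest.stage_counts[stage] = {
                t: {"pct_best": round(s.attrs["pct_best"], 2)} for t, s in sel_tables.items()
            }
            manifest.timings[stage] = round(time.time() - t0, 3)

            if data["pheno_offspring"] is not None:
                stage = "validate"
                t0 = time.time()
                val_r = {}
                for trait in cfg.traits:
                    off = data["pheno_offspring"][trait]
                    ref_ph = float(off.median()) if data["truth"] is None else float(
                        cfg.sim.trait_means.get(trait, off.median())
                    )
                    val = gsopt.validate_offspring(sel_tables[trait], off, ref_ph)
                    val.to_csv(out / f"validation_{trait}.tsv", sep="\t", index=False)
                    val_r[trait] = round(val.attrs["prediction_offspring_r"], 4)
                manifest.stage_counts[stage] = {"prediction_offspring_r": val_r}
                manifest.results["offspring_r"] = val_r
                manifest.timings[stage] = round(time.time() - t0, 3)

        if data["gff3"] is not None:
            stage = "annotate"
            t0 = time.time()
            trait0 = cfg.traits[0]
            target = common_train.get(trait0, panels[trait0])
            annos = annot.annotate(target, data["gff3"], data["fasta"],
                                   updown_bp=cfg.updown_bp)
            genic, props = annot.genic_subset(annos, target)
            pd.DataFrame([vars(a) for a in annos]).to_csv(
                out / "annotations.tsv", sep="\t", index=False
            )
            with open(out / "class_proportions.json", "wt") as fh:
                json.dump(props, fh, indent=2)
            manifest.stage_counts[stage] = {
                "annotated": len(annos), "genic": genic.n_markers,
                "pct_intergenic": round(100 * props.get("intergenic", 0.0), 2),
            }
            manifest.timings[stage] = round(time.time() - t0, 3)

            stage = "panels"
            t0 = time.time()
            grid0 = grids[trait0]
            best_tst, _ = grid0.best_cell
            accs = {}
            rnd = annot.random_marker_subset(target, genic.n_markers, seed=cfg.seed + 17)
            for name, mat in (("full", target), ("genic", genic), ("random", rnd)):
                gc = gsopt.GridConfig(
                    trait=trait0, tst_sizes=(best_tst,), pemv_levels=(0,),
                    n_iter=cfg.grid_iters, maf_min=0.0, seed=cfg.seed + 23,
                )
                res = gsopt.holdout_grid(mat, pheno, gc)
                accs[name] = round(float(res.mean_accuracy.iloc[0, 0]), 4)
            manifest.stage_counts[stage] = accs
            manifest.results["panel_accuracies"] = accs
            manifest.timings[stage] = round(time.time() - t0, 3)

        stage = "qtl"
        t0 = time.time()
        trait = cfg.qtl_trait
        qtl_geno = common_train.get(trait, panels.get(trait))
        # map and scan run on the unimputed trinary matrix
        base = panels[trait]
        keep = base.markers["id"].isin(qtl_geno.markers["id"]).to_numpy()
        base = base.subset_markers(keep)
        y = pheno[trait].loc[list(base.line_ids)].to_numpy(dtype=float)
        gmap = qtlmap.estimate_map(base)
        sc = qtlmap.ScanConfig(
            step_cM=cfg.qtl_step_cM, window_cM=cfg.qtl_window_cM,
            n_marcovar=cfg.qtl_n_marcovar, n_perm=cfg.qtl_n_perm,
            alpha=cfg.qtl_alpha, seed=cfg.seed + 31,
        )
        curve = qtlmap.cim_scan(base, y, gmap, sc)
        curve.threshold = qtlmap.permutation_threshold(base, y, gmap, sc, method="sim")
        curve.table.to_csv(out / "qtl_scan.tsv", sep="\t", index=False)
        hits = qtlmap.summarize_qtl(curve)
        pd.DataFrame([vars(h) for h in hits]).to_csv(out / "qtl_hits.tsv", sep="\t", index=False)
        manifest.stage_counts[stage] = {
            "threshold": round(curve.threshold, 4), "n_qtl": len(hits),
            "max_lod": round(curve.max_lod(), 4),
        }
        manifest.results["qtl"] = manifest.stage_counts[stage]
        manifest.timings[stage] = round(time.time() - t0, 3)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        manifest.save(out / "manifest.partial.json")
        raise StageFailure(stage, manifest, exc) from exc

    manifest.outputs = {p.name: p.stat().st_size for p in sorted(out.iterdir())}
    manifest.save(out / "manifest.json")
    return manifest
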