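"""One-command orchestration of the paired-web analysis.

For every control/drought pair the pipeline runs the replicated
alignment, the degree-preserving null ensemble and z-score, link
classification and species turnover, node metrics, the per-species
rewiring table, the aligned matrix layout, and the aligned-region
summary; pooled tables then feed the three mixed-model families, and a
cross-pair summary reports mean +/- SD S^3. Every stage is seeded from
the single configured seed, so the whole report is a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .alignment import GAParams, align_replicated, write_alignment
from .foodweb import FoodWeb, web_summary
from .io import read_foodweb
from .layout import binary_matrices, matrix_long_table, order_control_species
from .metrics import metrics_table
from .null_models import null_alignment_scores
from .rewiring import (aligned_region_summary, classify_links,
                       link_class_table, rewiring_per_species, species_turnover)
from .stats import (ModelResult, StatsError, results_table,
                    rewiring_regression, specialism_regression,
                    treatment_comparison)
from .synthetic import GeneratorParams, generate_study

logger = logging.getLogger(__name__)

#: scaled-down defaults for interactive use; ``paper_settings`` restores
#: population 15000 / 2000 generations / 30 runs.
DEFAULT_GA = dict(population_size=500, generations=300, elite_fraction=0.5, n_runs=5)
PAPER_GA = dict(population_size=15000, generations=2000, elite_fraction=0.5, n_runs=30)


@dataclass
class PipelineConfig:
    input_dir: Optional[Path] = None
    generator: Optional[GeneratorParams] = None
    ga: GAParams = field(default_factory=lambda: GAParams(**DEFAULT_GA))
    null_n: int = 30
    do_null: bool = True
    do_stats: bool = True
    do_layout: bool = True
    out_dir: Path = Path("fwalign_report")
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls()
        if "input_dir" in doc:
            cfg.input_dir = Path(doc["input_dir"])
        if "generator" in doc and doc["generator"] is not None:
            cfg.generator = GeneratorParams(**doc["generator"])
        if "ga" in doc and doc["ga"] is not None:
            cfg.ga = GAParams(**doc["ga"])
        for key in ("null_n", "do_null", "do_stats", "do_layout", "seed", "log_level"):
            if key in doc:
                setattr(cfg, key, doc[key])
        if "out_dir" in doc:
            cfg.out_dir = Path(doc["out_dir"])
        return cfg


def discover_pairs(input_dir: Path) -> list[tuple[FoodWeb, FoodWeb]]:
    """Load control/drought pairs from a study directory.

    Uses ``manifest.yaml`` when present; otherwise pairs web files named
    ``C<block>_nodes.csv`` / ``D<block>_nodes.csv``. Unpaired webs are a
    hard error listing the orphans.
    """
    input_dir = Path(input_dir)
    webdir = input_dir / "webs" if (input_dir / "webs").is_dir() else input_dir
    manifest_path = input_dir / "manifest.yaml"
    pairs: list[tuple[str, str, int]] = []
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh)
        for entry in manifest["webs"]:
            pairs.append((entry["control"], entry["drought"], int(entry["block"])))
    else:
        ids = sorted(p.name[: -len("_nodes.csv")]
                     for p in webdir.glob("*_nodes.csv"))
        controls = {i[1:]: i for i in ids if i.startswith("C")}
        droughts = {i[1:]: i for i in ids if i.startswith("D")}
        orphans = sorted(
            [controls[b] for b in controls.keys() - droughts.keys()]
            + [droughts[b] for b in droughts.keys() - controls.keys()]
            + [i for i in ids if not i.startswith(("C", "D"))]
        )
        if orphans:
            raise ValueError(f"unpaired web file(s): {orphans}")
        for b in sorted(controls.keys() & droughts.keys()):
            pairs.append((controls[b], droughts[b], int(b) if b.isdigit() else 0))
    if not pairs:
        raise ValueError(f"no control/drought pairs found under {input_dir}")

    out = []
    for cid, did, block in pairs:
        control = read_foodweb(webdir / f"{cid}_nodes.csv", webdir / f"{cid}_links.csv",
                               web_id=cid, treatment="control", block=block)
        drought = read_foodweb(webdir / f"{did}_nodes.csv", webdir / f"{did}_links.csv",
                               web_id=did, treatment="drought", block=block)
        out.append((control, drought))
    return out


def orient_pair(control: FoodWeb, drought: FoodWeb):
    """Return (G1, G2) undirected graphs, smaller first (ties: drought)."""
    Gc, Gd = control.to_undirected(), drought.to_undirected()
    if Gc.number_of_nodes() < Gd.number_of_nodes():
        return Gc, Gd
    return Gd, Gc


@dataclass
class PairReport:
    pair_id: str
    s3_mean: float
    s3_sd: float
    s3_best: float
    z: Optional[float]
    null_mu: Optional[float]
    null_sigma: Optional[float]
    turnover: dict
    n_conserved: int
    n_lost: int
    n_rewired: int
    n_invader_links: int


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        pairs_syn, _ = generate_study(config.generator, outdir=out / "synthetic_study")
        pairs = [(p.control, p.drought) for p in pairs_syn]
    elif config.input_dir is not None:
        pairs = discover_pairs(config.input_dir)
    else:
        raise ValueError("config needs either input_dir or generator settings")

    root = np.random.SeedSequence(config.seed)
    pair_seeds = root.spawn(len(pairs))

    pair_reports: list[PairReport] = []
    metric_rows: list[pd.DataFrame] = []
    species_tables: list[pd.DataFrame] = []

    for (control, drought), seq in zip(pairs, pair_seeds):
        pair_id = f"{control.web_id}|{drought.web_id}"
        pair_dir = out / f"pair_{control.web_id}_{drought.web_id}"
        pair_dir.mkdir(exist_ok=True)
        s_align, s_null = (int(x) for x in seq.generate_state(2) % (2**31))
        logger.info("pair %s: S=%d/%d L=%d/%d", pair_id,
                    control.S, drought.S, control.L, drought.L)

        G1, G2 = orient_pair(control, drought)
        ga = dataclasses.replace(config.ga, seed=s_align)
        rep = align_replicated(G1, G2, ga)
        write_alignment(rep.best, pair_dir / "alignment.tsv", ga)

        null_mu = null_sigma = z = None
        if config.do_null:
            ens = null_alignment_scores(
                control.to_undirected(), drought.to_undirected(),
                n=config.null_n, ga=dataclasses.replace(ga, n_runs=1),
                seed=s_null, observed=rep.best.s3,
            )
            null_mu, null_sigma, z = ens.mu, ens.sigma, ens.z
            pd.DataFrame({"replicate": range(1, len(ens.scores) + 1),
                          "s3": ens.scores}).to_csv(
                pair_dir / "null_scores.csv", index=False)

        cls = classify_links(control, drought)
        link_class_table(cls).to_csv(pair_dir / "link_classes.csv", index=False)
        turnover = species_turnover(control, drought)

        mc = metrics_table(control.to_undirected(), web_id=control.web_id)
        md = metrics_table(drought.to_undirected(), web_id=drought.web_id)
        mc.to_csv(pair_dir / "metrics_control.csv", index=False)
        md.to_csv(pair_dir / "metrics_drought.csv", index=False)

        sp = rewiring_per_species(control, drought, cls, metrics_c=mc, metrics_d=md)
        sp.insert(0, "web_pair", pair_id)
        sp.to_csv(pair_dir / "species_rewiring.csv", index=False)
        # control-web metrics of the surviving consumers, for family 3
        sp = sp.merge(
            mc[["species_id", "degree", "eigencentrality", "pagerank"]],
            on="species_id", how="left",
        )
        species_tables.append(sp)

        survivors = set(control.species) & set(drought.species)
        for web, table in ((control, mc), (drought, md)):
            t = table[table["species_id"].isin(survivors)].copy()
            t["web_pair"] = pair_id
            t["treatment"] = web.treatment
            t["is_consumer"] = [
                control.species[s].is_consumer for s in t["species_id"]
            ]
            metric_rows.append(t)

        if config.do_layout:
            layout = order_control_species(control, drought, rep.best)
            Mc, Md = binary_matrices(layout, control, drought)
            np.savetxt(pair_dir / "matrix_control.csv", Mc, fmt="%d", delimiter=",")
            np.savetxt(pair_dir / "matrix_drought.csv", Md, fmt="%d", delimiter=",")
            matrix_long_table(layout, control, drought, cls).to_csv(
                pair_dir / "matrix_cells.csv", index=False)

        region = aligned_region_summary(control, drought, rep.best)
        summ_rows = [dataclasses.asdict(web_summary(w)) for w in (control, drought)]
        pd.DataFrame(summ_rows).to_csv(pair_dir / "web_summary.csv", index=False)
        with open(pair_dir / "aligned_region.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(region), fh)

        pair_reports.append(PairReport(
            pair_id=pair_id, s3_mean=rep.mean, s3_sd=rep.sd, s3_best=rep.best.s3,
            z=z, null_mu=null_mu, null_sigma=null_sigma,
            turnover=dataclasses.asdict(turnover),
            n_conserved=len(cls.conserved), n_lost=len(cls.lost),
            n_rewired=len(cls.rewired), n_invader_links=len(cls.invader_links),
        ))

    # ------------------------------------------------------------------
    metrics_long = pd.concat(metric_rows, ignore_index=True)
    metrics_long.to_csv(out / "metrics_long.csv", index=False)
    species_all = pd.concat(species_tables, ignore_index=True)
    species_all.to_csv(out / "species_rewiring_all.csv", index=False)

    model_results: list[ModelResult] = []
    if config.do_stats:
        for metric in ("degree", "eigencentrality", "pagerank"):
            for subset in ("all", "consumers", "resources"):
                try:
                    r = treatment_comparison(metrics_long, metric=metric, subset=subset)
                    r.response = f"{metric}[{subset}]"
                    model_results.append(r)
                except StatsError as exc:
                    logger.warning("treatment model %s/%s skipped: %s",
                                   metric, subset, exc)
        for resp in ("delta_degree", "delta_eigencentrality", "delta_pagerank"):
            try:
                model_results.append(rewiring_regression(species_all, response=resp))
            except StatsError as exc:
                logger.warning("rewiring model %s skipped: %s", resp, exc)
        for pred in ("degree", "eigencentrality", "pagerank"):
            try:
                model_results.append(specialism_regression(species_all, predictor=pred))
            except StatsError as exc:
                logger.warning("specialism model %s skipped: %s", pred, exc)
        if model_results:
            results_table(model_results).to_csv(out / "model_results.csv", index=False)

    s3_means = [r.s3_mean for r in pair_reports]
    summary = {
        "n_pairs": len(pair_reports),
        "s3_mean_over_pairs": float(np.mean(s3_means)),
        "s3_sd_over_pairs": float(np.std(s3_means, ddof=1)) if len(s3_means) > 1 else 0.0,
        "null_mu_mean": (float(np.mean([r.null_mu for r in pair_reports]))
                         if config.do_null else None),
        "z_mean": (float(np.mean([r.z for r in pair_reports]))
                   if config.do_null else None),
        "mean_prop_shared_species": float(np.mean(
            [r.turnover["prop_shared_species"] for r in pair_reports])),
        "mean_prop_shared_links": float(np.mean(
            [r.turnover["prop_shared_links"] for r in pair_reports])),
        "seed": config.seed,
        "pairs": [dataclasses.asdict(r) for r in pair_reports],
    }
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    pd.DataFrame([{k: v for k, v in dataclasses.asdict(r).items()
                   if k != "turnover"} for r in pair_reports]).to_csv(
        out / "pair_summary.csv", index=False)
    return summary
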