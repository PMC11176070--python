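"""End-to-end orchestration of the synthetic mSV analysis stages.

A single :class:`RunConfig` names the stages to run, their parameter
overrides and one global seed; :func:`run_pipeline` executes them in
dependency order at demo scale, writes every stage's outputs under the run
directory and returns a manifest recording parameters, per-stage seeds and
output file hashes. Rerunning the same config yields byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import Genome, make_bins, write_bed
from .io import gz_compression, write_json
from .simulate import (ConfigError, CreSimConfig, ExprSimConfig, NOSimConfig,
                       SimConfig, simulate_cre_haplotype_counts,
                       simulate_expression, simulate_no_matrix,
                       simulate_strand_cells)

logger = logging.getLogger(__name__)

#: canonical execution order; a stage may only consume artifacts of stages
#: listed before it.
STAGES = ("simulate_strand", "strand_sce", "hotspots",
          "simulate_no", "celltype", "enrichment",
          "simulate_cre", "cis",
          "simulate_expr", "cna")

REQUIRES = {
    "simulate_strand": (),
    "strand_sce": ("simulate_strand",),
    "hotspots": ("strand_sce",),
    "simulate_no": (),
    "celltype": ("simulate_no",),
    "enrichment": ("celltype",),
    "simulate_cre": (),
    "cis": ("simulate_cre",),
    "simulate_expr": (),
    "cna": ("simulate_expr",),
}


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream artifact."""


def stage_seed(stage: str, seed: int) -> int:
    """Deterministic per-stage seed: crc32 of the stage name XOR the global
    seed, kept below 2**31."""
    return (zlib.crc32(stage.encode()) ^ int(seed)) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    ``params`` maps stage name to a dict of overrides for that stage's
    defaults. Unknown stage names and unknown top-level keys are rejected;
    the config round-trips losslessly through YAML.
    """

    stages: list
    outdir: str
    seed: int = 0
    genome_build: str = "synthetic"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in list(self.stages) + list(self.params):
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}; known: {', '.join(STAGES)}")
        if len(set(self.stages)) != len(self.stages):
            raise ConfigError("duplicate stage in stage list")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"stages", "outdir"} - set(data)
        if missing:
            raise ConfigError(f"missing config keys: {sorted(missing)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _make(config_cls, defaults: dict, params: dict, seed: int):
    """Build a simulator config from defaults + overrides + derived seed."""
    try:
        return config_cls(**{**defaults, **params}, seed=seed)
    except TypeError as exc:
        raise ConfigError(f"bad parameters for {config_cls.__name__}: {exc}") from exc


def _check_params(stage: str, params: dict, allowed: set) -> None:
    unknown = set(params) - allowed
    if unknown:
        raise ConfigError(f"unknown parameters for stage {stage}: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# stage implementations: fn(params, seed, out, artifacts) -> {name: Path}

def _stage_simulate_strand(params, seed, out, art):
    defaults = dict(genome=[("chr1", 30_000_000), ("chr2", 30_000_000),
                            ("chr3", 30_000_000)],
                    n_cells=20, reads_per_cell=10_000.0)
    cfg = _make(SimConfig, defaults, params, seed)
    m, truth = simulate_strand_cells(cfg)
    art["strand_matrix"] = m
    art["strand_truth"] = truth
    art["genome"] = Genome.from_pairs(cfg.genome)
    w, c = out / "strand_W.tsv.gz", out / "strand_C.tsv.gz"
    m.write_tsv(w, c)
    t = out / "strand_truth.json"
    write_json(t, {"sce_positions": truth.sce_positions,
                   "ground_states": {f"{cell}|{ch}": s
                                     for (cell, ch), s in truth.ground_states.items()},
                   "msv_carriers": truth.msv_carriers})
    g = out / "genome.chrom.sizes"
    art["genome"].write_chrom_sizes(g)
    return {"strand_W": w, "strand_C": c, "strand_truth": t, "chrom_sizes": g}


def _stage_strand_sce(params, seed, out, art):
    from .strand import call_strand_states, detect_sces, sces_to_bed
    _check_params("strand_sce", params,
                  {"min_bins", "error_rate", "min_reads_per_chrom"})
    segments = call_strand_states(art["strand_matrix"], **params)
    res = detect_sces(segments)
    art["segments"] = segments
    art["sces"] = res.calls
    seg = out / "segments.tsv"
    pd.DataFrame([dataclasses.asdict(s) for s in segments]).to_csv(
        seg, sep="\t", index=False)
    bed = out / "sces.bed"
    write_bed(sces_to_bed(res.calls), bed)
    logger.info("strand_sce: %d segments, %d SCE calls, %d chromosomes for review",
                len(segments), len(res.calls), len(res.review))
    return {"segments": seg, "sces": bed}


def _stage_hotspots(params, seed, out, art):
    from .hotspots import bin_sce_counts, call_hotspots, fit_hotspot_model
    _check_params("hotspots", params, {"bin_width", "alpha"})
    bins = make_bins(art["genome"], int(params.get("bin_width", 500_000)))
    counts = bin_sce_counts(art["sces"], bins)
    model = fit_hotspot_model(counts)
    table = call_hotspots(counts, model, bins, alpha=float(params.get("alpha", 0.05)))
    art["hotspot_table"] = table
    t = out / "hotspots.tsv"
    table.to_csv(t, sep="\t", index=False)
    mj = out / "hotspot_model.json"
    write_json(mj, {"size": model.nb_size, "mu": model.nb_mu, "loglik": model.loglik})
    logger.info("hotspots: fitted NB(size=%.3f, mu=%.3f), %d hotspot bins",
                model.nb_size, model.nb_mu, int(table["is_hotspot"].sum()))
    return {"hotspot_table": t, "hotspot_model": mj}


def _stage_simulate_no(params, seed, out, art):
    defaults = dict(n_classes=4, n_cells=120, n_genes=400, signature_size=20)
    cfg = _make(NOSimConfig, defaults, params, seed)
    m, truth = simulate_no_matrix(cfg)
    art["no_matrix"] = m
    art["no_truth"] = truth
    c = out / "no_counts.tsv.gz"
    m.counts.to_csv(c, sep="\t", compression=gz_compression(c))
    lab = out / "no_labels.tsv"
    pd.Series(truth.celltype_labels, name="cell_type").rename_axis("cell") \
        .to_csv(lab, sep="\t")
    t = out / "no_truth.json"
    write_json(t, {"signature_genes": truth.signature_genes,
                   "signature_effect": truth.signature_effect})
    return {"no_counts": c, "no_labels": lab, "no_truth": t}


def _stage_celltype(params, seed, out, art):
    from .celltyping import (normalize_no, select_features_stage1,
                             select_features_stage2, train_classifier)
    _check_params("celltype", params, {"n_perm"})
    n_perm = int(params.get("n_perm", 10))
    m = art["no_matrix"]
    labels = pd.Series(art["no_truth"].celltype_labels)
    z = normalize_no(m)
    s1 = select_features_stage1(z, labels, n_perm=n_perm, seed=seed)
    _, signature = select_features_stage2(z, labels, s1.selected_genes,
                                          n_perm=n_perm, seed=seed)
    if not signature:
        raise ValueError("celltype: two-stage selection returned no genes")
    clf = train_classifier(m, labels, signature)
    posterior = clf.classify(m)
    art["celltype_posterior"] = posterior
    art["signature"] = signature
    sig = out / "signature_genes.txt"
    sig.write_text("\n".join(signature) + "\n")
    post = out / "celltype_posterior.tsv"
    posterior.rename_axis("cell").to_csv(post, sep="\t")
    logger.info("celltype: %d signature genes, %d cells classified",
                len(signature), len(posterior))
    return {"signature": sig, "posterior": post}


def _stage_enrichment(params, seed, out, art):
    from .enrichment import subclone_enrichment
    _check_params("enrichment", params, {"subclone_size", "bias", "n_perm", "fdr"})
    posterior = art["celltype_posterior"]
    population = pd.DataFrame({"cell": posterior.index,
                               "cell_type": posterior["assigned"].to_numpy()})
    # demonstration subclone: sampled with the first cell type over-weighted,
    # so the run exercises a positive enrichment call
    bias = float(params.get("bias", 3.0))
    size = int(params.get("subclone_size", 30))
    rng = np.random.default_rng(seed)
    first = sorted(population["cell_type"].unique())[0]
    w = np.where(population["cell_type"] == first, bias, 1.0)
    sub = rng.choice(population["cell"], size=min(size, len(population)),
                     replace=False, p=w / w.sum())
    res = subclone_enrichment(sub, population,
                              n_perm=int(params.get("n_perm", 10_000)),
                              seed=seed, fdr=float(params.get("fdr", 0.10)))
    t = out / "enrichment.tsv"
    res.to_csv(t, sep="\t", index=False)
    return {"enrichment": t}


def _stage_simulate_cre(params, seed, out, art):
    defaults = dict(planted_windows=[("chrX", 1_000_000, 1_300_000, "H1", 0.5)])
    cfg = _make(CreSimConfig, defaults, params, seed)
    counts, cres, truth = simulate_cre_haplotype_counts(cfg)
    art["cre_counts"] = counts
    art["cres"] = cres
    art["cre_truth"] = truth
    c = out / "cre_counts.tsv.gz"
    counts.to_csv(c, sep="\t", compression=gz_compression(c))
    b = out / "cres.bed"
    write_bed(cres[["chrom", "start", "end", "cre_id"]], b)
    t = out / "cre_truth.json"
    write_json(t, {"clone_labels": truth.clone_labels,
                   "cis_windows": truth.cis_windows})
    return {"cre_counts": c, "cres": b, "cre_truth": t}


def _stage_cis(params, seed, out, art):
    from .cis import make_windows, window_log_ratios, window_permutation_fdr
    _check_params("cis", params, {"window", "step", "n_perm", "fdr_threshold"})
    cres = art["cres"]
    region = (str(cres["chrom"].iloc[0]), int(cres["start"].min()),
              int(cres["end"].max()))
    windows = make_windows(region, size=int(params.get("window", 300_000)),
                           step=int(params.get("step", 10_000)))
    R = window_log_ratios(art["cre_counts"], cres, windows)
    genotype = pd.Series(art["cre_truth"].clone_labels).map(
        {"carrier": "mutant", "wt": "wt"})
    res = window_permutation_fdr(R, genotype,
                                 n_perm=int(params.get("n_perm", 200)),
                                 seed=seed,
                                 threshold=float(params.get("fdr_threshold", 0.1)))
    res = windows.loc[res["window"]].reset_index(drop=True).join(
        res.reset_index(drop=True).drop(columns="window"))
    art["cis_table"] = res
    t = out / "cis_windows.tsv"
    res.to_csv(t, sep="\t", index=False)
    sig = res[res["significant"]]
    b = out / "cis_significant.bed"
    write_bed(sig[["chrom", "start", "end"]], b)
    logger.info("cis: %d windows tested, %d significant", len(res), len(sig))
    return {"cis_windows": t, "cis_significant": b}


def _stage_simulate_expr(params, seed, out, art):
    defaults = dict(n_cells=600,
                    clones=[("loss", ("chr17", 0, 1_200_000), 0.5, 0.3)])
    cfg = _make(ExprSimConfig, defaults, params, seed)
    m, truth = simulate_expression(cfg)
    art["expr_matrix"] = m
    art["expr_truth"] = truth
    art["expr_clones"] = list(cfg.clones)
    c = out / "expr_counts.tsv.gz"
    m.counts.to_csv(c, sep="\t", compression=gz_compression(c))
    g = out / "expr_genes.bed"
    write_bed(m.gene_meta.reset_index()[["chrom", "start", "end", "gene"]], g)
    t = out / "expr_truth.json"
    write_json(t, {"clone_labels": truth.clone_labels})
    return {"expr_counts": c, "expr_genes": g, "expr_truth": t}


def _stage_cna(params, seed, out, art):
    from .cna import (assign_clones, clone_cell_fraction, flag_bimodal_regions,
                      normalize_expression, region_mixture_test)
    _check_params("cna", params, {"min_genes", "fdr", "posterior"})
    m = art["expr_matrix"]
    norm = normalize_expression(m)
    fits, rows = [], []
    for (cid, (chrom, s, e), dosage, _) in art["expr_clones"]:
        genes = m.gene_meta[(m.gene_meta["chrom"] == chrom)
                            & (m.gene_meta["start"] < e)
                            & (m.gene_meta["end"] > s)].index.tolist()
        fit = region_mixture_test(norm, genes, region_id=cid,
                                  min_genes=int(params.get("min_genes", 5)),
                                  counts=m.counts, seed=seed)
        fits.append((fit, dosage))
    flag_bimodal_regions([f for f, _ in fits], fdr=float(params.get("fdr", 0.01)))
    assignments = {}
    for fit, dosage in fits:
        row = {"region": fit.region_id, "n_expressed": fit.n_expressed,
               "skipped": fit.skipped, "lrt_p": fit.lrt_p, "q": fit.q,
               "bimodal": fit.bimodal, "cf": np.nan}
        if fit.bimodal:
            a = assign_clones(fit, dosage,
                              posterior_cutoff=float(params.get("posterior", 0.8)))
            assignments[fit.region_id] = a
            row["cf"] = clone_cell_fraction(a)
        rows.append(row)
    table = pd.DataFrame(rows)
    art["cna_table"] = table
    t = out / "cna_regions.tsv"
    table.to_csv(t, sep="\t", index=False)
    outputs = {"cna_regions": t}
    for rid, a in assignments.items():
        p = out / f"cna_assignments_{rid}.tsv"
        a.to_csv(p, sep="\t")
        outputs[f"cna_assignments_{rid}"] = p
    logger.info("cna: %s", table.to_dict("records"))
    return outputs


_STAGE_FN = {
    "simulate_strand": _stage_simulate_strand,
    "strand_sce": _stage_strand_sce,
    "hotspots": _stage_hotspots,
    "simulate_no": _stage_simulate_no,
    "celltype": _stage_celltype,
    "enrichment": _stage_enrichment,
    "simulate_cre": _stage_simulate_cre,
    "cis": _stage_cis,
    "simulate_expr": _stage_simulate_expr,
    "cna": _stage_cna,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    Stages run in canonical dependency order regardless of their order in
    the config; a stage whose upstream stage was not requested raises
    :class:`DependencyError`. The manifest (also written to
    ``outdir/manifest.json``) records per-stage seeds, parameters and a
    sha256 of every output file.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("scmosaic")
    root.addHandler(handler)
    try:
        requested = [s for s in STAGES if s in config.stages]
        artifacts: dict = {}
        done: set = set()
        manifest = {"genome_build": config.genome_build, "seed": config.seed,
                    "outdir": str(out), "stages": []}
        for stage in requested:
            missing = [d for d in REQUIRES[stage] if d not in done]
            if missing:
                raise DependencyError(
                    f"stage {stage!r} requires {missing} to run first; add "
                    "them to the stage list")
            seed = stage_seed(stage, config.seed)
            params = dict(config.params.get(stage, {}))
            logger.info("running stage %s (seed %d)", stage, seed)
            outputs = _STAGE_FN[stage](params, seed, out, artifacts)
            manifest["stages"].append({
                "name": stage, "seed": seed, "params": params,
                "outputs": {k: {"path": str(p.relative_to(out)),
                                "sha256": _sha256(p)}
                            for k, p in outputs.items()}})
            done.add(stage)
        write_json(out / "manifest.json", manifest)
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
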