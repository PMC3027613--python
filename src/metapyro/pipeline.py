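"""End-to-end pipeline: generate -> qc -> profile -> function ->
diversity -> variants -> coverage, driven by one declarative config.

Each stage reads the previous stage's in-memory products, writes its
outputs under the run directory, and contributes counts and output
checksums to a JSON run manifest.  One global seed is split into
per-stage substreams so stages are individually reproducible; reruns
with the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import coverage as cov
from . import diversity as div
from . import io as mio
from . import readqc, synthetic, taxonomy, variants
from .function import PathwayGroupMap, aggregate_pathway_tree, join_function_taxonomy

log = logging.getLogger("metapyro")

STAGES = ("generate", "qc", "profile", "function", "diversity", "variants", "coverage")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: str = "metapyro_run"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    community: dict[str, Any] = field(default_factory=dict)
    qc: dict[str, Any] = field(default_factory=dict)
    profile: dict[str, Any] = field(default_factory=lambda: {"rank": "genus", "min_confidence": 0.80})
    function: dict[str, Any] = field(default_factory=dict)
    diversity: dict[str, Any] = field(default_factory=lambda: {"iterations": 200, "subsample": 2000})
    variants: dict[str, Any] = field(default_factory=lambda: {"n_variants": 7, "n_reads": 132, "error_rate": 0.005})
    coverage: dict[str, Any] = field(default_factory=lambda: {"hgt_depletion": 0.8, "n_mapped_reads": 50000})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise PipelineError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        unknown = set(cfg.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages {sorted(unknown)}")
        return cfg


def demo_config(outdir: str, seed: int = 0) -> RunConfig:
    """The bundled demo: a 20k-read community with planted GC
    breakpoint, 10% duplicates, classifier noise, 7 marker variants and
    80% HGT depletion — every conservation law checkable in minutes."""
    cfg = RunConfig(outdir=outdir, seed=seed)
    cfg.community = {
        "n_reads": 20_000,
        "duplicate_rate": 0.10,
        "backfold_breakpoint": 400,
        "backfold_gc_drop": 0.004,
        "noise": 0.05,
        "conf_spread": 0.4,
    }
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write the run manifest.

    A stage failure aborts the run with the failing stage named; the
    partially written run directory keeps a ``.partial`` marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partial = outdir / ".partial"
    partial.touch()
    seeds = _stage_seeds(config.seed)
    manifest: dict[str, Any] = {"seed": config.seed, "stage_seeds": seeds, "stages": {}}
    state: dict[str, Any] = {}
    try:
        for stage in STAGES:
            if not config.stages.get(stage, True):
                log.info("stage %s disabled, skipping", stage)
                continue
            log.info("running stage %s", stage)
            runner = _RUNNERS[stage]
            try:
                entry = runner(config, seeds[stage], outdir, state)
            except Exception as exc:  # noqa: BLE001 - named-stage abort
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
            entry["outputs"] = {
                name: _sha256(outdir / name) for name in entry.get("files", [])
            }
            entry.pop("files", None)
            manifest["stages"][stage] = entry
    except PipelineError:
        raise
    finally:
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    partial.unlink(missing_ok=True)
    return manifest


# -- stage runners ----------------------------------------------------


def _community_spec(config: RunConfig, seed: int) -> synthetic.CommunitySpec:
    params = dict(config.community)
    params.pop("noise", None)
    params.pop("conf_spread", None)
    params.setdefault("seed", seed)
    return synthetic.default_community(**{
        k: v for k, v in params.items()
        if k in {"n_reads", "duplicate_rate", "backfold_breakpoint",
                 "backfold_gc_drop", "seed"}
    })


def _run_generate(config, seed, outdir: Path, state) -> dict:
    spec = _community_spec(config, seed)
    reads, truth = synthetic.generate_reads(spec)
    cm = synthetic.ConfidenceModel(
        noise=config.community.get("noise", 0.0),
        conf_spread=config.community.get("conf_spread", 0.0),
    )
    tax_table, cog_table = synthetic.generate_assignment_tables(
        reads, truth, spec, confidence_model=cm, seed=seed + 1
    )
    state.update(spec=spec, reads=reads, truth=truth,
                 tax_table=tax_table, cog_table=cog_table)
    mio.write_fasta(reads, outdir / "reads.fasta")
    mio.write_tsv(truth.table, outdir / "ground_truth.tsv")
    mio.write_tsv(tax_table, outdir / "tax_assignments.tsv")
    mio.write_tsv(cog_table, outdir / "cog_assignments.tsv")
    return {
        "params": {"n_reads": spec.n_reads, "duplicate_rate": spec.duplicate_rate,
                   "breakpoint": spec.backfold_breakpoint},
        "counts": {"reads": len(reads), "tax_rows": len(tax_table),
                   "cog_rows": len(cog_table)},
        "files": ["reads.fasta", "ground_truth.tsv", "tax_assignments.tsv",
                  "cog_assignments.tsv"],
    }


def _run_qc(config, seed, outdir: Path, state) -> dict:
    reads = state["reads"]
    params = readqc.QCParams(**config.qc)
    kept, report, endpoint = readqc.normalize_dataset(reads, params)
    state["filtered_reads"] = kept
    state["report"] = report
    mio.write_fasta(kept, outdir / "reads.filtered.fasta")
    profile = readqc.build_gc_profile(reads, params.min_reads_per_point)
    mio.write_tsv(profile.to_frame(), outdir / "gc_profile.tsv")
    (outdir / "filter_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True)
    )
    files = ["reads.filtered.fasta", "gc_profile.tsv", "filter_report.json"]
    if endpoint is not None:
        mio.write_tsv(endpoint.tested, outdir / "endpoint_scan.tsv")
        (outdir / "endpoint.json").write_text(
            json.dumps(endpoint.to_dict(), indent=2, sort_keys=True)
        )
        files += ["endpoint_scan.tsv", "endpoint.json"]
    return {"params": asdict(params), "counts": report.to_dict(), "files": files}


def _filtered_assignments(state) -> pd.DataFrame:
    kept_ids = {r.read_id for r in state["filtered_reads"]}
    tax = state["tax_table"]
    return tax[tax["read_id"].isin(kept_ids)]


def _run_profile(config, seed, outdir: Path, state) -> dict:
    rank = config.profile.get("rank", "genus")
    min_conf = config.profile.get("min_confidence", 0.80)
    tax = _filtered_assignments(state)
    at_rank = taxonomy.apply_confidence_threshold(tax, rank, min_conf)
    total = len(state["filtered_reads"])
    counts = at_rank.groupby("taxon").size().astype(int).to_dict()
    profile = taxonomy.AbundanceProfile(rank=rank, counts=counts, total_reads=total)
    state["profile"] = profile
    state["profile_assignments"] = at_rank
    frame = pd.DataFrame(
        {
            "taxon": list(profile.counts),
            "count": list(profile.counts.values()),
            "percent": [profile.percentage(t) for t in profile.counts],
        }
    ).sort_values("count", ascending=False, kind="stable")
    mio.write_tsv(frame, outdir / f"profile_{rank}.tsv")
    return {
        "params": {"rank": rank, "min_confidence": min_conf},
        "counts": {"assigned": int(sum(counts.values())), "taxa": len(counts),
                   "total_reads": total},
        "files": [f"profile_{rank}.tsv"],
    }


def _run_function(config, seed, outdir: Path, state) -> dict:
    tax = _filtered_assignments(state)
    tree = taxonomy.TaxonomyTree.from_lineages(
        [t.lineage for t in state["spec"].taxa]
    )
    nodes = taxonomy.lineage_table_to_nodes(tax, tree)
    kept_ids = {r.read_id for r in state["filtered_reads"]}
    cog = state["cog_table"]
    cog = cog[cog["read_id"].isin(kept_ids)]
    joined, join_report = join_function_taxonomy(cog, nodes)
    gmap = PathwayGroupMap.default()
    files = []
    counts: dict[str, Any] = dict(join_report)
    for pathway in ("polysaccharide_degradation", "acetogenesis", "methanogenesis"):
        ftree = aggregate_pathway_tree(joined, tree, gmap, pathway)
        name = f"function_{pathway}.tsv"
        mio.write_tsv(ftree.to_frame().sort_values("node", kind="stable"), outdir / name)
        files.append(name)
        counts[f"n_{pathway}"] = ftree.total_reads
    state["joined"] = joined
    state["taxonomy_tree"] = tree
    return {"params": {}, "counts": counts, "files": files}


def _run_diversity(config, seed, outdir: Path, state) -> dict:
    profile = state["profile"]
    at_rank = state["profile_assignments"]
    tax = _filtered_assignments(state)
    rank = profile.rank
    all_at_rank = tax[tax["rank"] == rank]
    h = div.shannon_index(profile)
    iterations = config.diversity.get("iterations", 200)
    subsample = min(config.diversity.get("subsample", 2000), len(all_at_rank))
    h_sub = div.subsampled_shannon(
        all_at_rank, subsample, iterations=iterations, seed=seed, mode="category"
    )
    curve = div.rarefaction_curve(list(profile.counts.values()))
    mio.write_tsv(curve.to_frame(), outdir / "rarefaction_genera.tsv")
    result = {
        "shannon": h,
        "subsampled_shannon": h_sub,
        "subsample_size": int(subsample),
        "iterations": int(iterations),
        "n_taxa": len(profile.counts),
    }
    (outdir / "diversity.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    state["diversity"] = result
    return {"params": {"iterations": iterations, "subsample": subsample},
            "counts": {"n_taxa": len(profile.counts)},
            "files": ["rarefaction_genera.tsv", "diversity.json"]}


def _run_variants(config, seed, outdir: Path, state) -> dict:
    n_variants = config.variants.get("n_variants", 7)
    n_reads = config.variants.get("n_reads", 132)
    error_rate = config.variants.get("error_rate", 0.005)
    reference = synthetic.make_marker_reference(seed=seed)
    defs = synthetic.default_variant_defs(reference, n_variants=n_variants, seed=seed + 1)
    marker_reads, truth = synthetic.generate_variant_reads(
        reference, defs, n_reads, error_rate=error_rate, seed=seed + 2
    )
    groups, consensus, aligned = variants.bin_variants(marker_reads, reference)
    state["variant_groups"] = groups
    state["variant_truth"] = truth
    rows = [
        {"group": f"variant_{k + 1}", "n_reads": len(g.members),
         "n_snps": len(g.signature),
         "members": ",".join(sorted(g.members))}
        for k, g in enumerate(groups)
    ]
    mio.write_tsv(pd.DataFrame(rows), outdir / "variant_groups.tsv")
    cons_reads = [readqc.Read(name, seq) for name, seq in consensus.items()]
    mio.write_fasta(cons_reads, outdir / "variant_consensus.fasta")
    return {
        "params": {"n_variants": n_variants, "n_reads": n_reads, "error_rate": error_rate},
        "counts": {"groups": len(groups),
                   "reads_binned": sum(len(g.members) for g in groups)},
        "files": ["variant_groups.tsv", "variant_consensus.fasta"],
    }


def _run_coverage(config, seed, outdir: Path, state) -> dict:
    depletion = config.coverage.get("hgt_depletion", 0.8)
    n_mapped = config.coverage.get("n_mapped_reads", 50_000)
    genome = synthetic.make_reference_genome(seed=seed)
    mapping = synthetic.generate_mapping(
        genome, n_reads=n_mapped, hgt_depletion=depletion, seed=seed + 1
    )
    intervals = list(zip(mapping["start"], mapping["end"]))
    frac = cov.covered_fraction(intervals, genome.length)
    records = cov.gene_normalized_coverage(intervals, genome.genes)
    comparison = cov.compare_hgt_density(records)
    rec_frame = pd.DataFrame(
        [
            {"gene_id": r.gene_id, "length": r.length, "mapped_bases": r.mapped_bases,
             "hgt": r.hgt, "normalized_coverage": r.normalized_coverage}
            for r in records
        ]
    )
    mio.write_tsv(rec_frame, outdir / "gene_coverage.tsv")
    dens = pd.DataFrame(
        {
            "x": comparison.density_all.grid,
            "density_all": comparison.density_all.density,
            "density_hgt": (comparison.density_hgt.density
                            if comparison.density_hgt else np.nan),
            "density_other": (comparison.density_other.density
                              if comparison.density_other else np.nan),
        }
    )
    mio.write_tsv(dens, outdir / "coverage_density.tsv")
    summary = {"covered_fraction": frac, **comparison.summary}
    (outdir / "coverage_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    state["coverage_summary"] = summary
    return {
        "params": {"hgt_depletion": depletion, "n_mapped_reads": n_mapped},
        "counts": {"mapped_reads": len(mapping), "genes": len(records)},
        "files": ["gene_coverage.tsv", "coverage_density.tsv", "coverage_summary.json"],
    }


_RUNNERS = {
    "generate": _run_generate,
    "qc": _run_qc,
    "profile": _run_profile,
    "function": _run_function,
    "diversity": _run_diversity,
    "variants": _run_variants,
    "coverage": _run_coverage,
}
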