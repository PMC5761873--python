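"""End-to-end orchestration: one config in, a report bundle out.

``run_all`` wires the stages together — read processing, context
annotation, composition profiles, cluster detection, conservation,
differential expression and the target cascade — writing TSV/BED
outputs plus a JSON manifest with parameters, seed, per-stage record
counts and output checksums.  Optional inputs (e.g. the conservation
track) degrade to an explicitly "skipped" stage; a failing stage aborts
with its name.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotation, clusters, conservation, diffexpr, read_processing, targets
from .intervals import Feature, GenomicInterval
from .io import read_gmt, read_regulator_table, write_bed
from .read_processing import PiRNARecord

DEFAULT_PARAMS: dict[str, Any] = {
    "min_len": 16,
    "max_len": 40,
    "window": 20_000,
    "step": 1_000,
    "min_distinct": 10,
    "fc_threshold": 1.5,
    "alpha": 0.05,
    "expr_fc_threshold": 2.0,
    "expr_alpha": 0.05,
    "sc_min": 170.0,
    "en_max": -20.0,
    "seed_rule": "gu_and_mismatch",
    "priority": list(annotation.DEFAULT_PRIORITY),
}

_REQUIRED_PATHS = ("genome", "pirna_reference")
_OPTIONAL_PATHS = (
    "conservation", "expression", "expression_groups", "transcripts",
    "transcript_regions", "gene_map", "transcript_repeats", "regulators",
    "disease_sets", "pathway_sets",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def validate_config(config: dict) -> list[str]:
    """Return every violated constraint at once (empty list = ok)."""
    errors: list[str] = []
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    for key in ("window", "step", "min_distinct"):
        if not isinstance(params[key], int) or params[key] <= 0:
            errors.append(f"parameter {key!r} must be a positive integer")
    for key in ("alpha", "expr_alpha"):
        if not 0 < params[key] <= 1:
            errors.append(f"parameter {key!r} must lie in (0, 1]")
    for key in ("fc_threshold", "expr_fc_threshold"):
        if params[key] <= 0:
            errors.append(f"parameter {key!r} must be positive")
    if params["seed_rule"] not in ("gu_and_mismatch", "combined"):
        errors.append("parameter 'seed_rule' must be 'gu_and_mismatch' or 'combined'")
    if params["min_len"] > params["max_len"]:
        errors.append("min_len must not exceed max_len")
    if not config.get("reads"):
        errors.append("config needs a 'reads' mapping of sample -> FASTQ path")
    if not config.get("samples"):
        errors.append("config needs a 'samples' mapping of sample -> case/control")
    for key in _REQUIRED_PATHS:
        p = config.get(key)
        if not p:
            errors.append(f"config key {key!r} is required")
        elif not Path(p).exists():
            errors.append(f"path for {key!r} does not exist: {p}")
    for sample, path in (config.get("reads") or {}).items():
        if not Path(path).exists():
            errors.append(f"reads path for sample {sample!r} does not exist: {path}")
    for key in _OPTIONAL_PATHS:
        p = config.get(key)
        if p and not Path(p).exists():
            errors.append(f"path for {key!r} does not exist: {p}")
    for cat, path in (config.get("tracks") or {}).items():
        if not Path(path).exists():
            errors.append(f"track path for {cat!r} does not exist: {path}")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g",
              index=index_label is not None, index_label=index_label)


def run_all(config: dict) -> dict:
    """Run every stage the config provides inputs for; return the manifest."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(f"- {e}" for e in errors))
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    outdir = Path(config.get("output_dir", "pirome_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.get("seed"),
        "parameters": params,
        "stages": {},
        "outputs": {},
    }

    def done(stage: str, n: int) -> None:
        manifest["stages"][stage] = {"status": "completed", "n_records": int(n)}

    def skipped(stage: str, why: str) -> None:
        manifest["stages"][stage] = {"status": "skipped", "reason": why}

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    # ------------------------------------------------ 1. read processing
    try:
        from .io import read_fasta
        genome = read_fasta(config["genome"])
        reference = read_processing.read_reference_fasta(config["pirna_reference"])
        samples_reads = {}
        for sample in config["reads"]:
            reads = read_processing.load_reads(config["reads"][sample])
            samples_reads[sample] = read_processing.filter_by_length(
                reads, params["min_len"], params["max_len"])
        records, unassigned = read_processing.annotate_known_pirnas(
            samples_reads, reference)
        records.sort(key=lambda r: r.id)
        for rec in records:
            alns = read_processing.map_unique([(rec.id, rec.sequence)], genome)
            rec.loci = [a.interval for a in alns]
        records = [r for r in records if r.loci]
    except Exception as exc:   # noqa: BLE001 - stage attribution
        raise PipelineError("read_processing", str(exc)) from exc
    done("read_processing", len(records))

    # ------------------------------------------------ 2. context annotation
    tracks: list[annotation.AnnotationTrack] = []
    try:
        for cat, path in sorted((config.get("tracks") or {}).items()):
            tracks.append(annotation.AnnotationTrack.from_bed(cat, path))
        if tracks:
            annotation.annotate_records(records, tracks,
                                        tuple(params["priority"]))
            arch = annotation.architecture_summary(records)
            arch_df = pd.DataFrame(
                [(c, n, f) for c, (n, f) in arch.items()],
                columns=["context", "count", "fraction"])
            _write_tsv(arch_df, outdir / "architecture_summary.tsv")
            emit("architecture_summary", outdir / "architecture_summary.tsv")
            done("annotation", len(records))
        else:
            skipped("annotation", "no annotation tracks configured")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("annotation", str(exc)) from exc

    # piRNA table
    sample_names = list(config["reads"])
    pir_rows = []
    for rec in records:
        locus = rec.loci[0]
        pir_rows.append({
            "pirna_id": rec.id, "sequence": rec.sequence, "length": rec.length,
            "locus": f"{locus.chrom}:{locus.start}-{locus.end}({locus.strand})",
            "context": rec.context,
            **{f"count_{s}": rec.counts.get(s, 0) for s in sample_names},
        })
    _write_tsv(pd.DataFrame(pir_rows), outdir / "pirna_table.tsv")
    emit("pirna_table", outdir / "pirna_table.tsv")

    # ------------------------------------------------ 3. composition profiles
    try:
        hist = read_processing.length_histogram(records)
        _write_tsv(pd.DataFrame(sorted(hist.items()), columns=["length", "count"]),
                   outdir / "length_histogram.tsv")
        emit("length_histogram", outdir / "length_histogram.tsv")
        bias_rows = []
        for pos in (1, 10):
            freqs = read_processing.positional_base_freq(records, pos)
            for base, frac in freqs.items():
                bias_rows.append({"position": pos, "base": base, "fraction": frac})
        _write_tsv(pd.DataFrame(bias_rows), outdir / "positional_bias.tsv")
        emit("positional_bias", outdir / "positional_bias.tsv")
        labels, fractions = read_processing.biogenesis_signature(records)
        _write_tsv(pd.DataFrame(sorted(fractions.items()),
                                columns=["signature", "fraction"]),
                   outdir / "biogenesis_signature.tsv")
        emit("biogenesis_signature", outdir / "biogenesis_signature.tsv")
    except Exception as exc:
        raise PipelineError("composition", str(exc)) from exc
    done("composition", len(records))

    # ------------------------------------------------ 4. clusters
    try:
        loci = [(rec.id, iv) for rec in records for iv in rec.loci]
        found = clusters.detect_clusters(
            loci, params["window"], params["step"], params["min_distinct"])
        for cl in found:
            clusters.annotate_cluster_contents(cl, tracks)
        feats = [Feature(c.interval, f"cluster_{i + 1}")
                 for i, c in enumerate(found)]
        write_bed(outdir / "clusters.bed", feats)
        emit("clusters_bed", outdir / "clusters.bed")
        cl_rows = [{
            "cluster": f"cluster_{i + 1}",
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "length_nt": clusters.cluster_length(c),
            "n_members": c.n_members,
            "n_plus": c.strand_counts[0],
            "n_minus": c.strand_counts[1],
            "repeat_exclusive": c.repeat_exclusive,
            "members": ",".join(sorted(c.members)),
            "contained": ";".join(
                f"{cat}:{','.join(names)}"
                for cat, names in sorted(c.contained_features.items())),
        } for i, c in enumerate(found)]
        _write_tsv(pd.DataFrame(cl_rows), outdir / "clusters.tsv")
        emit("clusters_tsv", outdir / "clusters.tsv")
    except Exception as exc:
        raise PipelineError("clusters", str(exc)) from exc
    done("clusters", len(found))

    # ------------------------------------------------ 5. conservation
    if config.get("conservation"):
        try:
            track = conservation.ConservationTrack.from_bedgraph(
                config["conservation"])
            scored = []
            for rec in records:
                score = conservation.mean_conservation(rec.loci[0], track)
                if score is not None:
                    scored.append((rec.id, rec.context or "unknown", score))
            _write_tsv(pd.DataFrame(scored,
                                    columns=["pirna_id", "context", "mean_score"]),
                       outdir / "conservation_scores.tsv")
            emit("conservation_scores", outdir / "conservation_scores.tsv")
            summaries = conservation.summarize_by_context(scored)
            _write_tsv(pd.DataFrame([vars(s) for s in summaries]),
                       outdir / "conservation_summary.tsv")
            emit("conservation_summary", outdir / "conservation_summary.tsv")
        except Exception as exc:
            raise PipelineError("conservation", str(exc)) from exc
        done("conservation", len(scored))
    else:
        skipped("conservation", "no conservation track configured")

    # ------------------------------------------------ 6. differential expression
    de_pirnas = None
    try:
        counts = pd.DataFrame(
            {s: [r.counts.get(s, 0) for r in records] for s in sample_names},
            index=[r.id for r in records])
        factors = diffexpr.size_factors(counts)
        res = diffexpr.nb_test_noreplicates(counts, factors, config["samples"])
        de_pirnas = diffexpr.call_de(res, params["fc_threshold"], params["alpha"])
        _write_tsv(de_pirnas, outdir / "de_pirnas.tsv", index_label="pirna_id")
        emit("de_pirnas", outdir / "de_pirnas.tsv")
    except Exception as exc:
        raise PipelineError("de_pirnas", str(exc)) from exc
    done("de_pirnas", int((de_pirnas["status"] != "unchanged").sum()))

    de_genes = None
    if config.get("expression") and config.get("expression_groups"):
        try:
            matrix = pd.read_csv(config["expression"], sep="\t", index_col=0)
            grp = pd.read_csv(config["expression_groups"], sep="\t")
            groups = dict(zip(grp["sample"], grp["group"]))
            de_genes = diffexpr.de_genes_expression_matrix(
                matrix, groups, params["expr_fc_threshold"], params["expr_alpha"])
            _write_tsv(de_genes, outdir / "de_genes.tsv", index_label="gene_id")
            emit("de_genes", outdir / "de_genes.tsv")
        except Exception as exc:
            raise PipelineError("de_genes", str(exc)) from exc
        done("de_genes", int((de_genes["status"] != "unchanged").sum()))
    else:
        skipped("de_genes", "no expression matrix configured")

    # ------------------------------------------------ 7. target cascade
    cascade_inputs = ("transcripts", "transcript_regions", "transcript_repeats",
                      "regulators", "disease_sets", "pathway_sets")
    if de_genes is not None and all(config.get(k) for k in cascade_inputs):
        try:
            gene_map = {}
            if config.get("gene_map"):
                gm = pd.read_csv(config["gene_map"], sep="\t")
                gene_map = dict(zip(gm["transcript_id"], gm["gene_id"]))
            txs = targets.load_transcripts(
                config["transcripts"], config["transcript_regions"], gene_map)
            repeats = targets.parse_repeatmasker_out(config["transcript_repeats"])
            regulators = read_regulator_table(config["regulators"])
            disease_sets = read_gmt(config["disease_sets"])
            pathway_sets = read_gmt(config["pathway_sets"])
            up = {r.id: r.sequence for r in records
                  if de_pirnas.loc[r.id, "status"] == "up"}
            down_genes = de_genes.index[de_genes["status"] == "down"].tolist()
            final, logs = targets.run_cascade(
                up, down_genes, txs, repeats, regulators, disease_sets,
                pathway_sets, universe=de_genes.index,
                sc_min=params["sc_min"], en_max=params["en_max"],
                seed_rule=params["seed_rule"])
            _write_tsv(final, outdir / "targets.tsv")
            emit("targets", outdir / "targets.tsv")
            _write_tsv(pd.DataFrame([vars(l) for l in logs]),
                       outdir / "cascade_trace.tsv")
            emit("cascade_trace", outdir / "cascade_trace.tsv")
        except Exception as exc:
            raise PipelineError("targets", str(exc)) from exc
        done("targets", len(final))
    else:
        skipped("targets", "cascade inputs incomplete")

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def write_pipeline_config(truth, outdir: Path, seed: int) -> Path:
    """Emit a ready-to-run pipeline config pointing at simulated files."""
    cfg = {
        "seed": seed,
        "output_dir": str(outdir / "results"),
        "samples": dict(truth.config.samples),
        "reads": {s: truth.paths[f"reads:{s}"] for s in truth.config.samples},
        "genome": truth.paths["genome"],
        "pirna_reference": truth.paths["pirna_reference"],
        "tracks": {k.split(":", 1)[1]: v for k, v in truth.paths.items()
                   if k.startswith("track:")},
        "conservation": truth.paths.get("conservation"),
        "expression": truth.paths.get("expression"),
        "expression_groups": truth.paths.get("expression_groups"),
        "transcripts": truth.paths.get("transcripts"),
        "transcript_regions": truth.paths.get("transcript_regions"),
        "gene_map": truth.paths.get("gene_map"),
        "transcript_repeats": truth.paths.get("transcript_repeats"),
        "regulators": truth.paths.get("regulators"),
        "disease_sets": truth.paths.get("disease_sets"),
        "pathway_sets": truth.paths.get("pathway_sets"),
    }
    path = outdir / "pipeline_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
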