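"""End-to-end orchestration: mine -> design primers -> annotate ->
(optionally) call inter-variety polymorphisms -> (optionally) diversity.

Each stage writes its outputs before the next starts, and the manifest
records per-stage input/output counts so the marker-development funnel
(contigs -> SSR loci -> designed markers -> validation panel) can be read
directly from a run.  Parameters come from a single flat-namespace
configuration, loadable from YAML with unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import io as gio
from .annotation import classify_ssr_region, find_longest_orf
from .diversity import (
    binary_band_matrix,
    diversity_report,
    jaccard_similarity_matrix,
    upgma,
)
from .mining import MiningParams, mine_contigs, select_validation_panel, summarize_frequencies
from .polymorphism import filter_calls, match_shared_loci
from .primers import PrimerParams, assign_marker_ids, design_primers

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

__version__ = "0.1.0"

logger = logging.getLogger("genicssr")


@dataclass
class PipelineConfig:
    """All pipeline parameters in one place.

    Stage toggles select what runs; the polymorphism stage needs
    ``variety_b_fasta`` and the diversity stage ``allele_matrix``.
    """

    contigs_fasta: str | None = None
    variety_b_fasta: str | None = None
    allele_matrix: str | None = None
    group_labels: Mapping[str, str] | None = None
    output_dir: str = "genicssr_out"
    run_mining: bool = True
    run_primers: bool = True
    run_annotation: bool = True
    run_polymorphism: bool = False
    run_diversity: bool = False
    mining: MiningParams = field(default_factory=MiningParams)
    primers: PrimerParams = field(default_factory=PrimerParams)
    panel_min_len: int = 18
    min_orf_len: int = 150
    anchor_len: int = 25
    poly_min_len: int = 20
    poly_min_diff: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config from YAML; unknown keys raise ``ValueError``."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("pipeline config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub_cls in (("mining", MiningParams), ("primers", PrimerParams)):
            if key in raw and isinstance(raw[key], dict):
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(raw[key]) - sub_known
                if sub_unknown:
                    raise ValueError(f"unknown {key} keys: {sorted(sub_unknown)}")
                # YAML lists become tuples where the dataclass expects them
                coerced = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw[key].items()
                }
                raw[key] = sub_cls(**coerced)
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["group_labels"] = dict(self.group_labels) if self.group_labels else None
        return d


@dataclass
class RunManifest:
    """Record of one pipeline run: per-stage record counts and outputs."""

    version: str
    config_hash: str
    stages: list[dict[str, Any]] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def add(self, stage: str, n_in: int, n_out: int, outputs: list[str]) -> None:
        self.stages.append(
            {"stage": stage, "n_in": n_in, "n_out": n_out, "outputs": outputs}
        )
        logger.info("stage %-14s in=%-6d out=%-6d", stage, n_in, n_out)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in order, writing each stage's
    outputs before the next starts.  A stage failure aborts the run with
    the stage name in the error."""
    manifest = RunManifest(version=__version__, config_hash=_config_hash(config))
    manifest.started = _now()
    outdir = Path(config.output_dir)

    for path in (config.contigs_fasta, config.variety_b_fasta, config.allele_matrix):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"configured input does not exist: {path}")

    needs_contigs = (
        config.run_mining
        or config.run_primers
        or config.run_annotation
        or config.run_polymorphism
    )
    if needs_contigs and config.contigs_fasta is None:
        raise ValueError("contigs_fasta is required for the enabled stages")
    if not (needs_contigs or config.run_diversity):
        manifest.finished = _now()
        return manifest
    outdir.mkdir(parents=True, exist_ok=True)

    contigs = loci = markers = None
    if needs_contigs:
        contigs = gio.read_fasta(config.contigs_fasta)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if config.run_mining or config.run_primers or config.run_polymorphism:
        def mine():
            found = mine_contigs(contigs, config.mining)
            out = outdir / "loci.tsv"
            gio.write_tsv(gio.loci_to_frame(found), out)
            total_bp = sum(len(c) for c in contigs)
            summary = summarize_frequencies(found, total_bp, len(contigs))
            gio.write_tsv(summary.by_unit_length, outdir / "freq_by_unit.tsv", index=True)
            gio.write_tsv(summary.by_class, outdir / "freq_by_class.tsv", index=True)
            manifest.add("mine", len(contigs), len(found),
                         [str(out), str(outdir / "freq_by_unit.tsv"),
                          str(outdir / "freq_by_class.tsv")])
            return found

        loci = _stage("mine", mine)

    if config.run_primers:
        def primers_stage():
            by_id = {c.id: c for c in contigs}
            designed = []
            for locus in loci:
                pair = design_primers(by_id[locus.contig_id], locus, config.primers)
                if pair is not None:
                    designed.append((locus, pair))
            defs = assign_marker_ids(designed)
            out = outdir / "markers.tsv"
            gio.write_tsv(gio.markers_to_frame(defs), out)
            manifest.add("primers", len(loci), len(defs), [str(out)])
            panel = [
                m for m in defs
                if m.locus.length >= config.panel_min_len
            ]
            pout = outdir / "validation_panel.tsv"
            gio.write_tsv(gio.markers_to_frame(panel), pout)
            manifest.add("panel", len(defs), len(panel), [str(pout)])
            return defs

        markers = _stage("primers", primers_stage)

    if config.run_annotation:
        def annotate():
            rows = []
            orfs = {
                c.id: find_longest_orf(c.sequence, config.min_orf_len, c.id)
                for c in contigs
            }
            items = markers if markers is not None else []
            if not items and loci is not None:
                items = loci
            for item in items:
                locus = item.locus if hasattr(item, "locus") else item
                orf = orfs.get(locus.contig_id)
                region = classify_ssr_region(locus, orf)
                rows.append(
                    {
                        "marker_id": getattr(item, "marker_id", ""),
                        "contig_id": locus.contig_id,
                        "strand": orf.strand if orf else "NA",
                        "cds_start": orf.cds_start + 1 if orf else "NA",
                        "cds_end": orf.cds_end if orf else "NA",
                        "region": region,
                    }
                )
            out = outdir / "annotation.tsv"
            gio.write_tsv(pd.DataFrame(rows), out)
            manifest.add("annotate", len(items), len(rows), [str(out)])
            return rows

        _stage("annotate", annotate)

    if config.run_polymorphism:
        def inpoly():
            contigs_b = gio.read_fasta(config.variety_b_fasta)
            calls, skipped = match_shared_loci(
                contigs, loci, contigs_b, anchor_len=config.anchor_len
            )
            gio.write_tsv(gio.calls_to_frame(calls), outdir / "polymorphism_calls.tsv")
            manifest.add("inpoly_match", len(loci), len(calls),
                         [str(outdir / "polymorphism_calls.tsv")])
            retained = filter_calls(calls, config.poly_min_len, config.poly_min_diff)
            out = outdir / "polymorphism_retained.tsv"
            gio.write_tsv(gio.calls_to_frame(retained), out)
            manifest.add("inpoly_filter", len(calls), len(retained), [str(out)])
            return retained

        if config.variety_b_fasta is None:
            raise ValueError("variety_b_fasta is required for the polymorphism stage")
        _stage("inpoly", inpoly)

    if config.run_diversity:
        def diversity_stage():
            matrix = gio.read_allele_matrix(config.allele_matrix)
            groups = config.group_labels or {g: "all" for g in matrix.index}
            report = diversity_report(matrix, groups)
            gio.write_tsv(report.round(4), outdir / "diversity_report.tsv", index=True)
            bands, _ = binary_band_matrix(matrix)
            sim = jaccard_similarity_matrix(bands)
            gio.write_tsv(sim.round(4), outdir / "similarity.tsv", index=True)
            tree = upgma(1.0 - sim)
            gio.write_newick(tree, outdir / "upgma.nwk")
            manifest.add(
                "diversity", matrix.shape[0], len(report) - 1,
                [str(outdir / "diversity_report.tsv"), str(outdir / "similarity.tsv"),
                 str(outdir / "upgma.nwk")],
            )
            return report

        if config.allele_matrix is None:
            raise ValueError("allele_matrix is required for the diversity stage")
        _stage("diversity", diversity_stage)

    manifest.finished = _now()
    manifest.to_json(outdir / "manifest.json")
    return manifest
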