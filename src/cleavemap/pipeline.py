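"""End-to-end orchestration: synthesize -> map -> call -> quantify -> model.

Every randomized stage consumes a stream seeded deterministically from the
single top-level seed, so one config + seed pair reproduces every output
table byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import genome_io, linker, promoter, seqsignals, synthetic, tonks
from .genome_io import ChromosomeSpec, Profile
from .occupancy2d import Anchor, build_2d_occupancy
from .promoter import NDRCall

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Top-level run configuration; see ``from_yaml`` for the file schema."""

    seed: int
    output_dir: str
    synthetic: dict[str, Any] = field(default_factory=dict)
    ndr: dict[str, Any] = field(default_factory=dict)
    linker: dict[str, Any] = field(default_factory=dict)
    model: dict[str, Any] = field(default_factory=dict)
    fit: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("config must set a top-level seed")
        return cls(
            seed=int(raw["seed"]),
            output_dir=str(raw.get("output_dir", "results")),
            synthetic=raw.get("synthetic", {}) or {},
            ndr=raw.get("ndr", {}) or {},
            linker=raw.get("linker", {}) or {},
            model=raw.get("model", {}) or {},
            fit=raw.get("fit", {}) or {},
        )


# ---------------------------------------------------------------------------
# stage-artifact readers/writers (TSV, so runs round-trip through files)
# ---------------------------------------------------------------------------

def write_ndr_calls(calls: Sequence[NDRCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            (c.gene_id, c.chrom, c.strand, c.center, c.run_width, c.width,
             c.minus_one, c.plus_one)
            for c in calls
        ],
        columns=["gene_id", "chrom", "strand", "center", "run_width", "width",
                 "minus_one", "plus_one"],
    ).to_csv(path, sep="\t", index=False)


def read_ndr_calls(path: str | Path) -> list[NDRCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        NDRCall(r.gene_id, r.chrom, r.strand, int(r.center), int(r.run_width),
                int(r.width), int(r.minus_one), int(r.plus_one))
        for r in df.itertuples(index=False)
    ]


def write_nuc_calls_bed(calls, path: str | Path) -> None:
    """Refined +1/-1 calls as BED6 (name=gene_id:role, score=template score)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.dyad - 1}\t{c.dyad}\t{c.gene_id}:{c.role}\t"
                f"{c.score:.4f}\t+\n"
            )


def read_chrom_sizes(path: str | Path) -> list[ChromosomeSpec]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, length = line.split()[:2]
                out.append(ChromosomeSpec(name, int(length)))
    return out


def write_chrom_sizes(genome: Sequence[ChromosomeSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in genome:
            fh.write(f"{c.name}\t{c.length}\n")


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def _build_synthetic_config(cfg: PipelineConfig) -> synthetic.SyntheticConfig:
    kw = dict(cfg.synthetic)
    world_keys = {k: kw.pop(k) for k in ("n_genes", "gene_spacing", "n_cells")
                  if k in kw}
    return synthetic.default_world(cfg.seed, **world_keys, **kw)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the run manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "python": platform.python_version(),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = "ok"

    # --- simulate -----------------------------------------------------------
    stage("simulate")
    scfg = _build_synthetic_config(cfg)
    cells = synthetic.generate_chromatin(scfg)
    frags = synthetic.cleave(cells, scfg)
    seq = synthetic.generate_sequence(scfg)
    genome = scfg.genome
    genome_io.write_fragments(frags, out / "fragments.bed")
    genome_io.write_annotation(scfg.genes, out / "annotation.tsv")
    genome_io.write_fasta(seq, out / "genome.fa")
    write_chrom_sizes(genome, out / "chrom.sizes")
    manifest["n_fragments"] = len(frags)

    # --- dyads & occupancy --------------------------------------------------
    stage("dyads")
    dyads = genome_io.dyads_from_fragments(frags, genome)
    dyads_norm = genome_io.normalize_profile(dyads)
    occ = genome_io.normalize_profile(genome_io.occupancy_from_dyads(dyads))
    genome_io.write_track(dyads, out / "dyads.bedgraph")
    genome_io.write_track(occ, out / "occupancy.bedgraph")

    # --- NDR / +1 / -1 ------------------------------------------------------
    stage("ndr")
    ndr_calls = promoter.detect_ndrs(occ, scfg.genes, dyads, **cfg.ndr)
    refined = promoter.refine_calls(dyads, ndr_calls)
    refined_by_gene = {(c.gene_id, c.role): c for c in refined}
    ndr_calls = [
        NDRCall(
            c.gene_id, c.chrom, c.strand, c.center, c.run_width, c.width,
            refined_by_gene[(c.gene_id, "-1")].dyad,
            refined_by_gene[(c.gene_id, "+1")].dyad,
        )
        for c in ndr_calls
    ]
    write_ndr_calls(ndr_calls, out / "ndr_calls.tsv")
    write_nuc_calls_bed(refined, out / "nuc_calls.bed")
    manifest["n_ndr_calls"] = len(ndr_calls)

    # --- 2D occupancy at +1 anchors ----------------------------------------
    stage("occupancy2d")
    anchors = [Anchor(c.gene_id, c.chrom, c.plus_one, c.strand) for c in ndr_calls]
    lp = build_2d_occupancy(frags, anchors, window=(-300, 700))
    lp.to_frame().to_csv(out / "occupancy_2d.tsv", sep="\t")

    # --- gap / NRL / spacing ------------------------------------------------
    stage("linker")
    gap = linker.estimate_gap(frags, genome)
    pd.DataFrame({"lag": gap.lags, "correlation": gap.correlation}).to_csv(
        out / "gap_correlation.tsv", sep="\t", index=False
    )
    spectrum = linker.nrl_spectrum(frags, gap)
    pd.DataFrame(
        {"length": spectrum.lengths, "count": spectrum.histogram,
         "smoothed": spectrum.smoothed}
    ).to_csv(out / "nrl_spectrum.tsv", sep="\t", index=False)
    manifest["gap"] = gap.gap
    manifest["modal_nrls"] = spectrum.modal_nrls

    min_frags = int(cfg.linker.get("min_fragments_per_gene", 100))
    scores = linker.per_gene_spacing(frags, scfg.genes, min_fragments=min_frags)
    pd.DataFrame(
        [(s.gene_id, s.n_long_fragments, s.mean_long_length) for s in scores],
        columns=["gene_id", "n_long_fragments", "mean_long_length"],
    ).to_csv(out / "per_gene_spacing.tsv", sep="\t", index=False)
    if len(scores) >= 5:
        qt = linker.quintile_summary(scores, dyads_norm, ndr_calls, genes=scfg.genes)
        qt.to_csv(out / "quintiles.tsv", sep="\t", index=False)

    # --- rotational phasing -------------------------------------------------
    stage("dinuc")
    prof = seqsignals.dinucleotide_phasing(dyads, seq)
    prof.to_frame().to_csv(out / "dinucleotide_profile.tsv", sep="\t", index=False)

    # --- hard-rod model -----------------------------------------------------
    stage("model")
    params = tonks.BarrierParams(**cfg.model) if cfg.model else tonks.YEAST_BARRIER
    outputs = tonks.predict_genome(ndr_calls, params, genome)
    genome_io.write_track(
        Profile({c.name: outputs[c.name].occ for c in genome}),
        out / "model_occupancy.bedgraph",
    )
    if cfg.fit.get("enabled", False):
        stage("fit")
        fit = tonks.fit_barrier(
            dyads_norm, ndr_calls, genome[0],
            seed=cfg.seed,
            maxiter=int(cfg.fit.get("maxiter", 20)),
            popsize=int(cfg.fit.get("popsize", 8)),
        )
        with open(out / "fitted_params.yaml", "w") as fh:
            yaml.safe_dump(
                {"H": fit.params.H, "sigma": fit.params.sigma,
                 "x0": fit.params.x0, "u_minus_mu": fit.params.u_minus_mu,
                 "correlation": fit.correlation, "seed": fit.seed,
                 "n_evaluations": fit.n_evaluations},
                fh,
            )
        manifest["fit_correlation"] = fit.correlation

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
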