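"""End-to-end pipeline: FASTA in, figure bundle out.

Stages: read + validate sequences -> attach gene annotation (table, external
predictor hook, or none) -> pairwise HSPs (internal engine or imported BLAST
tabular) -> S_G matrix -> guide tree (three or more sequences only) ->
tree-ordered automatic layout -> SVG rendering. Every artifact plus a
machine-readable manifest is written to the output directory. Gene and
function annotation stages are skippable; their absence only removes gene
arrows from the figure.
"""

from __future__ import annotations

import json
import logging
import shlex
import subprocess
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .layout import Layout, auto_layout
from .pairalign import AlignParams, HitSet, all_pairs, read_blast_tab, write_blast_tab
from .render import DisplayFilter, RenderOptions, build_figure, write_svg, write_tree_svg
from .seqio import InputError, SeqRecord, read_fasta, read_gene_table, validate_input_set
from .similarity import build_guide_tree, compute_sg, order_sequences, write_newick

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything that affects a pipeline run."""

    mode: str = "nucleotide"  # or "translated"
    evalue_max: float = 1e-2
    word_size: int = 0  # 0 -> engine default for the mode
    blast_tab: str | None = None  # precomputed hits instead of the engine
    gene_table: str | None = None
    gene_hook: str | None = None  # external command emitting a BED-like table
    circular_ids: list[str] = field(default_factory=list)
    min_identity_pct: float = 0.0
    min_bit_score: float = 0.0
    min_hit_length: int = 0
    px_per_kb: float = 20.0
    color_scheme: str = "identity"
    show_genes: bool = True
    show_dotplots: bool = True
    tree_layout: str = "rectangular"
    outdir: str = "syntelign_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.gene_table and self.gene_hook:
            raise ValueError("gene_table and gene_hook are mutually exclusive")

    def align_params(self) -> AlignParams:
        return AlignParams(
            mode=self.mode, evalue_max=self.evalue_max, word_size=self.word_size
        )

    def display_filter(self) -> DisplayFilter:
        return DisplayFilter(
            min_identity_pct=self.min_identity_pct,
            min_bit_score=self.min_bit_score,
            min_hit_length=self.min_hit_length,
        )

    def render_options(self) -> RenderOptions:
        return RenderOptions(
            px_per_kb=self.px_per_kb,
            color_scheme=self.color_scheme,
            show_genes=self.show_genes,
            show_dotplots=self.show_dotplots,
        )


def hook_external_genes(config: RunConfig, records: list[SeqRecord]) -> list[SeqRecord]:
    """Run an external gene-prediction command and attach its BED-like output.

    The command template may contain ``{fasta}`` and ``{out}`` placeholders;
    it must write a BED-like gene table to ``{out}``. Any failure (nonzero
    exit, malformed table) degrades to gene-free rendering with a warning.
    """
    if not config.gene_hook:
        return records
    from .seqio import write_fasta

    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "input.fasta"
        out = Path(tmp) / "genes.bed"
        write_fasta(records, fasta)
        cmd = config.gene_hook.format(fasta=shlex.quote(str(fasta)),
                                      out=shlex.quote(str(out)))
        try:
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                logger.warning(
                    "gene hook exited with status %d; continuing without genes: %s",
                    proc.returncode, proc.stderr.strip()[:500],
                )
                return records
            read_gene_table(out, records)
        except (InputError, OSError) as exc:
            logger.warning("gene hook output unusable (%s); continuing without genes", exc)
            for r in records:
                r.genes.clear()
    return records


def run_pipeline(config: RunConfig, fasta: str | Path) -> dict:
    """Run the full pipeline; returns the manifest dict.

    Writes to ``config.outdir``: hits.tsv (BLAST outfmt 6), sg_matrix.tsv,
    guide_tree.nwk + tree.svg (only for three or more sequences), layout.tsv,
    alignment.svg, run.log, and manifest.json.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_logger = logging.getLogger("syntelign")
    pkg_logger.addHandler(handler)
    pkg_logger.setLevel(config.log_level.upper())
    outputs: list[str] = []
    try:
        records = read_fasta(fasta, circular_ids=config.circular_ids)
        inputs = validate_input_set(records, mode=config.mode)
        logger.info("read %d sequences from %s", len(inputs), fasta)

        if config.gene_table:
            read_gene_table(config.gene_table, records)
        elif config.gene_hook:
            hook_external_genes(config, records)

        params = config.align_params()
        if config.blast_tab:
            hits = read_blast_tab(config.blast_tab, records, params)
            logger.info("imported hits from %s", config.blast_tab)
        else:
            hits = all_pairs(inputs, params)
        hits_path = outdir / "hits.tsv"
        write_blast_tab(hits, hits_path)
        outputs.append(hits_path.name)

        sim = compute_sg(hits, inputs)
        sg_path = outdir / "sg_matrix.tsv"
        sim.to_tsv(sg_path)
        outputs.append(sg_path.name)

        tree = None
        if len(inputs) >= 3:
            tree = build_guide_tree(sim)
            nwk_path = outdir / "guide_tree.nwk"
            nwk_path.write_text(write_newick(tree) + "\n")
            outputs.append(nwk_path.name)
            tree_svg = outdir / "tree.svg"
            write_tree_svg(tree, tree_svg, layout=config.tree_layout,
                           options=config.render_options())
            outputs.append(tree_svg.name)
        else:
            logger.info("two sequences: no guide tree is generated")

        order_ids = order_sequences(inputs, tree)
        ordered = [inputs.get(i) for i in order_ids]
        layout = auto_layout(ordered, hits)
        layout_path = outdir / "layout.tsv"
        layout.to_tsv(layout_path)
        outputs.append(layout_path.name)

        fig = build_figure(layout, hits, config.display_filter(),
                           config.render_options())
        svg_path = outdir / "alignment.svg"
        write_svg(fig, svg_path)
        outputs.append(svg_path.name)

        manifest = {
            "tool": "syntelign",
            "version": __version__,
            "input_fasta": str(fasta),
            "sequences": [
                {"id": r.id, "length": r.length, "circular": r.circular,
                 "n_genes": len(r.genes)}
                for r in inputs
            ],
            "config": asdict(config),
            "align_params": {
                "mode": params.mode, "word_size": params.word_size,
                "match": params.match, "mismatch": params.mismatch,
                "matrix_name": params.matrix_name, "xdrop": params.xdrop,
                "evalue_max": params.evalue_max,
                "lambda": params.lambda_, "K": params.K,
            },
            "order": order_ids,
            "seed": config.seed,
            "outputs": outputs + ["run.log", "manifest.json"],
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        logger.info("wrote %d artifacts to %s", len(outputs) + 2, outdir)
        return manifest
    finally:
        pkg_logger.removeHandler(handler)
        handler.close()
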