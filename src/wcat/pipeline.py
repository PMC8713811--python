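"""Orchestration of the analysis stages as one reproducible run.

A :class:`RunConfig` names the inputs, thresholds and stages; stages run in
the fixed order classify -> interfaces -> phylo -> pairs -> conserve, and
every numeric parameter is echoed into the JSON run report so results are
traceable.  Reports carry no timestamps; reruns with an identical
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .classifier import DEFAULT_TAU, MIN_LABEL_SCORE, classify_sequence, evaluate_interfaces
from .conservation import column_conservation
from .fileio import (
    calls_to_frame, domains_to_frame, profile_to_frame, read_fasta,
    supports_to_frame, write_tsv,
)
from .frames import default_schema, load_schema
from .mapper import MAPPING_THRESHOLD
from .pairs import DEFAULT_MAX_DISTANCE, find_head_to_head_pairs, match_exon_template, read_gff3
from .phylo import tree_with_supports

log = logging.getLogger("wcat")

STAGE_ORDER = ("classify", "interfaces", "phylo", "pairs", "conserve")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    stages: list = field(default_factory=list)
    fasta: str | None = None              # chains for classify/interfaces
    alignment: str | None = None          # aligned FASTA for phylo/conserve
    gff: str | None = None                # annotations for pairs
    schema: str | None = None             # signature schema JSON (None = packaged)
    alpha: str | None = None              # chain ids for the interfaces stage
    beta: str | None = None
    tau: float = DEFAULT_TAU
    min_score: float = MIN_LABEL_SCORE
    mapping_threshold: float = MAPPING_THRESHOLD
    max_distance: int = DEFAULT_MAX_DISTANCE
    correction: str = "NONE"
    bootstrap_replicates: int = 100
    seed: int = 0
    positions: list = field(default_factory=list)  # groove columns for conserve
    outdir: str = "wcat_out"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.stages:
            raise PipelineError("no stages selected")
        for s in self.stages:
            if s not in STAGE_ORDER:
                raise PipelineError(f"unknown stage {s!r}")
        if not 0 <= self.tau <= 1:
            raise PipelineError("tau must lie in [0, 1]")
        if not 0 < self.mapping_threshold < 1:
            raise PipelineError("mapping threshold must lie in (0, 1)")
        if self.max_distance < 0:
            raise PipelineError("max_distance must be >= 0")
        if self.bootstrap_replicates < 1:
            raise PipelineError("bootstrap_replicates must be >= 1")


def default_config_dict() -> dict:
    cfg = dataclasses.asdict(RunConfig())
    return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; returns (and writes) the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schema = load_schema(config.schema) if config.schema else default_schema()

    report = {
        "wcat_version": __version__,
        "seed": config.seed,
        "parameters": {
            "tau": config.tau,
            "min_score": config.min_score,
            "mapping_threshold": config.mapping_threshold,
            "max_distance": config.max_distance,
            "correction": config.correction,
            "bootstrap_replicates": config.bootstrap_replicates,
            "schema_version": schema.version,
        },
        "stages": {},
    }

    calls = None
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        try:
            if stage == "classify":
                if not config.fasta:
                    raise PipelineError("classify stage needs a FASTA input")
                chains = read_fasta(config.fasta)
                calls = [
                    classify_sequence(seq, schema, chain_id=name, tau=config.tau,
                                      min_score=config.min_score,
                                      threshold=config.mapping_threshold)
                    for name, seq in chains.items()
                ]
                write_tsv(calls_to_frame(calls), outdir / "calls.tsv")
                write_tsv(domains_to_frame(calls), outdir / "domains.tsv")
                report["stages"]["classify"] = {
                    "n_chains": len(calls),
                    "labels": {c.chain_id: c.label for c in calls},
                    "outputs": ["calls.tsv", "domains.tsv"],
                }
            elif stage == "interfaces":
                if calls is None:
                    raise PipelineError("interfaces stage requires the classify stage")
                if not (config.alpha and config.beta):
                    raise PipelineError("interfaces stage needs alpha and beta chain ids")
                by_id = {c.chain_id: c for c in calls}
                try:
                    alpha, beta = by_id[config.alpha], by_id[config.beta]
                except KeyError as exc:
                    raise PipelineError(f"chain id not classified: {exc}") from exc
                iface = evaluate_interfaces(alpha, beta, schema)
                payload = {
                    "alpha": iface.alpha_id,
                    "beta": iface.beta_id,
                    "interfaces": {
                        name: {
                            "verdict": v.verdict,
                            "matched": v.matched,
                            "unmatched": v.unmatched,
                        }
                        for name, v in iface.interfaces.items()
                    },
                }
                (outdir / "interfaces.json").write_text(json.dumps(payload, indent=1))
                report["stages"]["interfaces"] = {
                    "verdicts": iface.verdicts(),
                    "outputs": ["interfaces.json"],
                }
            elif stage == "phylo":
                if not config.alignment:
                    raise PipelineError("phylo stage needs an aligned FASTA input")
                alignment = read_fasta(config.alignment)
                tree, support = tree_with_supports(
                    alignment, B=config.bootstrap_replicates, seed=config.seed,
                    correction=config.correction,
                )
                tree.write(str(outdir / "tree.nwk"))
                write_tsv(supports_to_frame(support), outdir / "supports.tsv")
                report["stages"]["phylo"] = {
                    "n_taxa": len(alignment),
                    "replicates": support.replicates,
                    "rng": support.generator,
                    "outputs": ["tree.nwk", "supports.tsv"],
                }
            elif stage == "pairs":
                if not config.gff:
                    raise PipelineError("pairs stage needs a GFF3 input")
                genes = read_gff3(config.gff)
                matching = [
                    g for g in genes if match_exon_template(g, "CLASS_II_TYPE")[0]
                ]
                pair_calls = find_head_to_head_pairs(matching, max_distance=config.max_distance)
                import pandas as pd

                df = pd.DataFrame([
                    {
                        "minus_gene": p.minus_gene, "plus_gene": p.plus_gene,
                        "contig": p.contig, "distance_bp": p.distance,
                        "orientation": p.orientation,
                    }
                    for p in pair_calls
                ], columns=["minus_gene", "plus_gene", "contig", "distance_bp", "orientation"])
                write_tsv(df, outdir / "pairs.tsv")
                report["stages"]["pairs"] = {
                    "n_genes": len(genes),
                    "n_template_matching": len(matching),
                    "n_pairs": len(pair_calls),
                    "pairs": [list(p.genes) for p in pair_calls],
                    "outputs": ["pairs.tsv"],
                }
            elif stage == "conserve":
                if not config.alignment:
                    raise PipelineError("conserve stage needs an aligned FASTA input")
                alignment = read_fasta(config.alignment)
                profile = column_conservation(alignment)
                write_tsv(profile_to_frame(profile), outdir / "conservation.tsv")
                entry = {
                    "n_columns": profile.n_columns,
                    "outputs": ["conservation.tsv"],
                }
                if config.positions:
                    entry["positions"] = list(config.positions)
                report["stages"]["conserve"] = entry
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
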