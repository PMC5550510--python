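"""End-to-end orchestration: preprocess -> DE -> votes -> consensus ->
enrichment -> motif enrichment, from a YAML run configuration.

Every threshold used is logged, each stage reports row counts in and
out (so filter attrition is auditable), and a run manifest records the
config snapshot, input digests, stage timings and output files.
Re-running with identical inputs, config and seed reproduces
byte-identical analysis tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from votesig.enrichment import GeneSetCollection, enrich_list, enrichment_to_tsv
from votesig.expression import ExpressionMatrix, log2_transform, quantile_normalize, read_expression_table
from votesig.motifs import PromoterSet, load_motifs, motif_enrichment, motif_enrichment_to_tsv
from votesig.signature import (
    Contrast,
    PipelineConfig,
    call_de_table,
    compute_contrast,
    consensus,
    log2fc_matrix,
    tally_votes,
)
from votesig.synthetic import (
    SyntheticParams,
    default_planted_motif,
    generate_dataset,
    generate_genesets,
    generate_promoters,
    random_decoy_motifs,
)
from votesig.motifs import write_motifs

__all__ = ["RunManifest", "run_pipeline", "simulate"]

log = logging.getLogger("votesig")


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    version: str = "votesig-0.1.0"

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_config(config_path: str | Path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "contrasts" not in cfg:
        raise ValueError(f"{config_path}: config must be a mapping with a 'contrasts' list")
    return cfg


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the full analysis described by a YAML config.

    Config keys: ``contrasts`` (list of {name, expression, groups,
    treated, control}), ``thresholds`` (PipelineConfig fields),
    ``quantile_normalize`` (default true), optional ``genesets`` (GMT),
    ``promoters`` (FASTA keyed by gene id), ``motifs`` (JASPAR counts),
    ``out_dir``.
    """
    cfg = _load_config(config_path)
    base = Path(config_path).parent
    out = Path(out_dir or cfg.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    thresholds = dict(cfg.get("thresholds", {}))
    pconf = PipelineConfig(**thresholds)
    manifest = RunManifest(config={**thresholds, "quantile_normalize": cfg.get("quantile_normalize", True)},
                           seed=pconf.seed)
    log.info(
        "thresholds: fc_log2=%s expr_floor=%s min_votes=%s window_half=%s alpha=%s p_adjust=%s mode=%s",
        pconf.fc_log2, pconf.expr_floor, pconf.min_votes, pconf.window_half,
        pconf.alpha, pconf.p_adjust, pconf.enrichment_mode,
    )

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    # --- preprocess + per-contrast stats -------------------------------
    stats_by_contrast: dict[str, object] = {}
    calls: dict[str, object] = {}
    t0 = time.perf_counter()
    try:
        for entry in cfg["contrasts"]:
            name = entry["name"]
            expr_path = resolve(entry["expression"])
            grp_path = resolve(entry["groups"])
            manifest.input_digests[str(expr_path)] = _sha256(expr_path)
            manifest.input_digests[str(grp_path)] = _sha256(grp_path)
            matrix = read_expression_table(expr_path, grp_path)
            if not cfg.get("already_log2", pconf.already_log2):
                matrix = log2_transform(matrix, offset=float(cfg.get("log2_offset", 1.0)))
            if cfg.get("quantile_normalize", True):
                matrix = quantile_normalize(matrix)
            contrast = Contrast(name=name, treated_group=entry["treated"], control_group=entry["control"])
            stats = compute_contrast(matrix, contrast)
            called = call_de_table(stats, name, pconf)
            n_de = int((called["direction"] != "none").sum())
            log.info("contrast %s: %d genes in, %d DE calls", name, len(stats), n_de)
            stats_by_contrast[name] = stats
            calls[name] = called
    except (KeyError, ValueError, OSError) as exc:
        raise StageError("differential_expression", exc) from exc
    manifest.stage_seconds["differential_expression"] = time.perf_counter() - t0

    # --- votes + consensus ---------------------------------------------
    t0 = time.perf_counter()
    try:
        votes = tally_votes(calls)
        if pconf.min_votes > votes.n_contrasts:
            log.warning(
                "min_votes (%d) exceeds the number of contrasts (%d); signatures will be empty",
                pconf.min_votes, votes.n_contrasts,
            )
        sig_up = consensus(votes, pconf, "up")
        sig_down = consensus(votes, pconf, "down")
        log.info(
            "votes: %d genes in universe; consensus up=%d down=%d (min_votes=%d)",
            len(votes.counts), len(sig_up.genes), len(sig_down.genes), pconf.min_votes,
        )
        votes.to_tsv(out / "votes.tsv")
        sig_up.to_tsv(out / "signature_up.tsv")
        sig_down.to_tsv(out / "signature_down.tsv")
        lfc = log2fc_matrix(stats_by_contrast)
        lfc.index.name = "gene_id"
        lfc.to_csv(out / "log2fc_matrix.tsv", sep="\t")
        manifest.outputs += ["votes.tsv", "signature_up.tsv", "signature_down.tsv", "log2fc_matrix.tsv"]
    except (ValueError, OSError) as exc:
        raise StageError("vote_counting", exc) from exc
    manifest.stage_seconds["vote_counting"] = time.perf_counter() - t0

    universe = list(votes.counts.index)

    # --- term enrichment (optional) ------------------------------------
    if cfg.get("genesets"):
        t0 = time.perf_counter()
        try:
            gmt_path = resolve(cfg["genesets"])
            manifest.input_digests[str(gmt_path)] = _sha256(gmt_path)
            collection = GeneSetCollection.from_gmt(gmt_path)
            if sig_up.gene_ids:
                rows = enrich_list(sig_up.gene_ids, collection, universe, pconf)
            else:
                rows = []
                log.warning("empty up signature; skipping term enrichment statistics")
            enrichment_to_tsv(rows, out / "enrichment.tsv")
            manifest.outputs.append("enrichment.tsv")
            log.info("enrichment: %d terms tested against %d-gene list", len(rows), len(sig_up.genes))
        except (ValueError, OSError) as exc:
            raise StageError("term_enrichment", exc) from exc
        manifest.stage_seconds["term_enrichment"] = time.perf_counter() - t0

    # --- motif enrichment (optional) -----------------------------------
    if cfg.get("promoters") and cfg.get("motifs"):
        t0 = time.perf_counter()
        try:
            prom_path = resolve(cfg["promoters"])
            mot_path = resolve(cfg["motifs"])
            manifest.input_digests[str(prom_path)] = _sha256(prom_path)
            manifest.input_digests[str(mot_path)] = _sha256(mot_path)
            promoters = PromoterSet.from_fasta(prom_path)
            pwms = load_motifs(mot_path)
            target = promoters.subset(sig_up.gene_ids)
            background = promoters.subset(g for g in promoters.windows if g not in target)
            if len(target):
                rows = motif_enrichment(target, background, pwms, pconf)
                motif_enrichment_to_tsv(rows, out / "motif_enrichment.tsv")
                manifest.outputs.append("motif_enrichment.tsv")
                log.info("motifs: %d motifs on %d target vs %d background promoters",
                         len(pwms), len(target), len(background))
            else:
                log.warning("no signature genes have promoters; skipping motif enrichment")
        except (ValueError, OSError) as exc:
            raise StageError("motif_enrichment", exc) from exc
        manifest.stage_seconds["motif_enrichment"] = time.perf_counter() - t0

    manifest.to_json(out / "manifest.json")
    return manifest


def simulate(params: SyntheticParams | str | Path, out_dir: str | Path, n_decoy_motifs: int = 10) -> Path:
    """Write a full synthetic input bundle (expression TSVs, group maps,
    promoter FASTA, GMT, motif file, truth record, run config)."""
    if not isinstance(params, SyntheticParams):
        with open(params) as fh:
            params = SyntheticParams(**(yaml.safe_load(fh) or {}))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, contrasts, truth = generate_dataset(params)
    entries = []
    for matrix, contrast in zip(matrices, contrasts):
        expr = f"expression_{contrast.name}.tsv"
        grp = f"groups_{contrast.name}.tsv"
        matrix.to_tsv(out / expr, out / grp)
        entries.append({
            "name": contrast.name, "expression": expr, "groups": grp,
            "treated": contrast.treated_group, "control": contrast.control_group,
        })
    motif = default_planted_motif()
    promoters = generate_promoters(truth, params, motif)
    promoters.to_fasta(out / "promoters.fasta")
    pwms = [motif] + random_decoy_motifs(n_decoy_motifs, motif.length, seed=params.seed + 1)
    write_motifs(pwms, out / "motifs.jaspar")
    collection = generate_genesets(truth)
    collection.to_gmt(out / "genesets.gmt")
    truth.to_txt(out / "truth.txt")
    config = {
        "contrasts": entries,
        "thresholds": {"seed": params.seed},
        "already_log2": True,
        "quantile_normalize": True,
        "genesets": "genesets.gmt",
        "promoters": "promoters.fasta",
        "motifs": "motifs.jaspar",
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return out / "config.yaml"
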