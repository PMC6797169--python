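"""End-to-end pipeline: clean -> lexicon -> networks -> auras -> homophily.

Backs the ``fmn run`` subcommand.  Every artifact of a run lands in one
output directory together with a manifest (configuration, seed, config
hash and record counts) sufficient to reproduce the run bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

from . import io as fio
from .errors import InputError
from .lexicon import build_lexicon
from .network import aura_table, build_network, export_network, filter_network
from .stats import aura_contrast, configuration_null_ensemble

log = logging.getLogger("fmnet")


@dataclass
class RunConfig:
    associations: Path
    ratings: Path
    outdir: Path
    norms: Path | None = None
    normalization_map: Path | None = None
    delimiter: str = "\t"
    max_blank_frac: float = 0.25
    warmup_k: int = 3
    alpha: float = 0.1
    min_participants: int = 2
    m_score: float = 1.0
    n_realisations: int = 50
    seed: int = 0
    aura_rule: str = "polarity"
    contrast: bool = False
    contrast_attribute: str = "negative"
    contrast_aura: str = "negative"
    networks_for_homophily: tuple[str, ...] = ("unfiltered", "filtered")

    def validate(self) -> None:
        if not 0.0 <= self.max_blank_frac <= 1.0:
            raise InputError("max_blank_frac must be in [0, 1]")
        if self.warmup_k < 0:
            raise InputError("warmup_k must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise InputError("alpha must be in (0, 1)")
        if self.min_participants < 1:
            raise InputError("min_participants must be >= 1")
        if self.contrast and self.norms is None:
            raise InputError(
                "aura contrast requested but no external norm table was given"
            )

    def to_dict(self) -> dict:
        out = asdict(self)
        for key in ("associations", "ratings", "outdir", "norms", "normalization_map"):
            if out[key] is not None:
                out[key] = str(out[key])
        out["networks_for_homophily"] = list(self.networks_for_homophily)
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the whole analysis; returns the output directory.

    Re-running with the same configuration (including the seed) reproduces
    every artifact, stochastic ones included, bit-exactly.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    counts: dict[str, int] = {}

    # --- cleaning ---------------------------------------------------------
    mapping = (
        fio.load_normalization_map(config.normalization_map)
        if config.normalization_map
        else None
    )
    assoc = fio.read_association_forms(config.associations, delimiter=config.delimiter)
    ratings = fio.read_rating_forms(config.ratings, delimiter=config.delimiter)
    counts["association_forms_read"] = len(assoc)
    counts["rating_forms_read"] = len(ratings)

    assoc = fio.normalize_tokens(assoc, mapping)
    ratings = fio.normalize_tokens(ratings, mapping)
    assoc = fio.drop_warmup(assoc, config.warmup_k)
    assoc, rej_assoc = fio.discard_incomplete_forms(assoc, config.max_blank_frac)
    ratings, rej_ratings = fio.discard_incomplete_forms(ratings, config.max_blank_frac)
    counts["association_forms_rejected"] = len(rej_assoc)
    counts["rating_forms_rejected"] = len(rej_ratings)
    log.info(
        "cleaning: %d association forms kept (%d rejected), "
        "%d rating forms kept (%d rejected)",
        len(assoc), len(rej_assoc), len(ratings), len(rej_ratings),
    )
    for name, obj in (
        ("cleaned_associations.tsv", assoc),
        ("cleaned_ratings.tsv", ratings),
    ):
        writer = (
            fio.write_association_forms
            if name.startswith("cleaned_a")
            else fio.write_rating_forms
        )
        writer(obj, outdir / name)
        artifacts.append(name)
    fio.write_rejection_log(rej_assoc, outdir / "rejections_associations.jsonl")
    fio.write_rejection_log(rej_ratings, outdir / "rejections_ratings.jsonl")
    artifacts += ["rejections_associations.jsonl", "rejections_ratings.jsonl"]
    overlap = {r["participant_id"] for r in rej_assoc} & {
        r["participant_id"] for r in rej_ratings
    }
    counts["participants_rejected_in_both_tasks"] = len(overlap)

    # --- lexicon ----------------------------------------------------------
    lexicon, skew = build_lexicon(ratings, alpha=config.alpha)
    lexicon.to_csv(outdir / "lexicon.csv")
    (outdir / "skew.json").write_text(
        json.dumps(asdict(skew), indent=2) + "\n", encoding="utf-8"
    )
    artifacts += ["lexicon.csv", "skew.json"]
    by_attr = {a: 0 for a in ("positive", "neutral", "negative")}
    for wv in lexicon.words.values():
        by_attr[wv.attribute] += 1
    counts.update({f"words_{a}": n for a, n in by_attr.items()})
    log.info("lexicon: %d words classified %s", len(lexicon), by_attr)

    # --- networks ---------------------------------------------------------
    unfiltered = build_network(assoc, lexicon)
    filtered = filter_network(unfiltered, config.min_participants)
    export_network(unfiltered, outdir / "network_unfiltered.graphml")
    export_network(filtered, outdir / "network_filtered.graphml")
    artifacts += ["network_unfiltered.graphml", "network_filtered.graphml"]
    counts["edges_unfiltered"] = unfiltered.number_of_edges()
    counts["edges_filtered"] = filtered.number_of_edges()
    counts["nodes_unfiltered"] = unfiltered.number_of_nodes()
    counts["nodes_filtered"] = filtered.number_of_nodes()
    log.info(
        "networks: %d/%d nodes, %d/%d edges (unfiltered/filtered)",
        counts["nodes_unfiltered"], counts["nodes_filtered"],
        counts["edges_unfiltered"], counts["edges_filtered"],
    )

    aura_table(
        unfiltered, sorted(unfiltered.nodes), rule=config.aura_rule
    ).to_csv(outdir / "aura_table.csv", index=False, encoding="utf-8")
    artifacts.append("aura_table.csv")

    # --- homophily --------------------------------------------------------
    graphs = {"unfiltered": unfiltered, "filtered": filtered}
    for label in config.networks_for_homophily:
        graph = graphs[label]
        if graph.number_of_edges() < 2:
            log.warning("skipping homophily on %s network: too few edges", label)
            continue
        for statistic in ("edge_endpoint_tau", "node_neighborhood_tau"):
            result = configuration_null_ensemble(
                graph,
                statistic=statistic,
                n_realisations=config.n_realisations,
                seed=config.seed,
                m=config.m_score,
            )
            name = f"homophily_{label}_{statistic}.json"
            result.to_json(outdir / name)
            artifacts.append(name)
            log.info(
                "homophily (%s, %s): tau=%.4f null mean=%.4f percentile=%.1f",
                label, statistic, result.tau_observed,
                result.null_mean, result.percentile_of_observed,
            )

    # --- aura contrast ----------------------------------------------------
    if config.contrast:
        norms = fio.read_norms(config.norms)
        results = {}
        for measure in ("valence", "arousal"):
            if measure == "arousal" and not norms.arousal:
                continue
            result = aura_contrast(
                unfiltered,
                norms,
                target_attribute=config.contrast_attribute,
                aura_condition=config.contrast_aura,
                measure=measure,
                aura_rule=config.aura_rule,
            )
            results[measure] = result.to_dict()
        (outdir / "aura_contrast.json").write_text(
            json.dumps(results, indent=2) + "\n", encoding="utf-8"
        )
        artifacts.append("aura_contrast.json")

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.config_hash(),
        "seed": config.seed,
        "counts": counts,
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return outdir
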