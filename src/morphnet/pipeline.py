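"""End-to-end pipeline orchestration: corpus -> networks -> measures -> models.

Every run writes a deterministic artifact bundle into an output
directory: the resolved configuration, a corpus summary, per-session
network edge lists, the measure table, activation timelines, the six
adaptation model tables (four node-level mixed models, two density
OLS models) and the machine-readable effect ledger.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .corpus import CorpusTable, read_session_tokens, summarize_corpus, write_session_tokens
from .measures import activation_timeline, measure_table
from .models import (
    DENSITY_RESPONSES,
    NODE_RESPONSES,
    assemble_network_frame,
    assemble_node_frame,
    effect_summary,
    fit_density_lm,
    fit_node_lmm,
)
from .networks import build_network_series, build_registry
from .simulate import SimParams, simulate_dyad

logger = logging.getLogger("morphnet")

_KNOWN_KEYS = {
    "corpus_path",
    "sim_params",
    "dyad_id",
    "adjacency_mode",
    "density_mode",
    "centrality_tol",
    "impute_prior",
    "exclude_predictors",
    "output_dir",
    "seed",
    "log_level",
}


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    Either ``corpus_path`` (a coded verb-token CSV/TSV) or ``sim_params``
    (simulate a corpus first) must be provided.
    """

    output_dir: str
    corpus_path: Optional[str] = None
    sim_params: Optional[SimParams] = None
    dyad_id: Optional[str] = None
    adjacency_mode: str = "binary"
    density_mode: str = "unipartite"
    centrality_tol: float = 1e-10
    impute_prior: str = "zero"
    exclude_predictors: dict = field(default_factory=dict)  # response -> [predictor]
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.corpus_path is None) == (self.sim_params is None):
            raise ValueError("provide exactly one of corpus_path or sim_params")
        if self.adjacency_mode not in ("binary", "weighted"):
            raise ValueError(f"unknown adjacency_mode {self.adjacency_mode!r}")
        if self.density_mode not in ("unipartite", "bipartite"):
            raise ValueError(f"unknown density_mode {self.density_mode!r}")
        if self.impute_prior not in ("zero", "drop"):
            raise ValueError(f"unknown impute_prior {self.impute_prior!r}")

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        if doc.get("sim_params") is not None and not isinstance(doc["sim_params"], SimParams):
            doc["sim_params"] = SimParams(**doc["sim_params"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle; returns artifact paths."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    resolved = config.to_dict()
    resolved["package_version"] = __version__
    (out / "config.json").write_text(json.dumps(resolved, indent=2, default=str))
    artifacts["config"] = str(out / "config.json")

    # --- corpus ---
    if config.sim_params is not None:
        table, truth = simulate_dyad(config.sim_params, seed=config.seed)
        write_session_tokens(table, out / "corpus.csv")
        truth.to_json(out / "ground_truth.json")
        artifacts["corpus"] = str(out / "corpus.csv")
        artifacts["ground_truth"] = str(out / "ground_truth.json")
    else:
        table = read_session_tokens(config.corpus_path)
    dyad = config.dyad_id or table.dyads[0]
    logger.info("corpus: %d records, dyad %s", len(table), dyad)

    summary = summarize_corpus(table, dyad)
    summary.to_frame().to_csv(out / "corpus_summary.csv", index=False)
    artifacts["corpus_summary"] = str(out / "corpus_summary.csv")

    # --- networks ---
    series = build_network_series(table, dyad, mode=config.adjacency_mode)
    logger.info("built %d networks over %d sessions", len(series), len(series.sessions))
    edges = pd.concat(
        [net.edge_list() for net in series.networks.values()], ignore_index=True
    )
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    artifacts["network_edges"] = str(out / "network_edges.tsv")
    for speaker in series.speakers:
        reg = build_registry(table, dyad, speaker)
        logger.info(
            "registry %s: %d roots, %d patterns",
            speaker,
            len(reg.roots),
            len(reg.patterns),
        )

    # --- measures ---
    measures = measure_table(series, density_mode=config.density_mode, tol=config.centrality_tol)
    measures.to_csv(out / "measures.csv", index=False)
    artifacts["measures"] = str(out / "measures.csv")
    for speaker in series.speakers:
        act = activation_timeline(series, speaker)
        act.stats.to_csv(out / f"activation_{speaker.lower()}.csv")
        artifacts[f"activation_{speaker.lower()}"] = str(
            out / f"activation_{speaker.lower()}.csv"
        )

    # --- models ---
    node_frame = assemble_node_frame(measures, impute_prior=config.impute_prior)
    net_frame = assemble_network_frame(measures)
    fits = []
    for response in NODE_RESPONSES:
        fit = fit_node_lmm(
            node_frame, response, exclude=config.exclude_predictors.get(response, ())
        )
        if not fit.converged:
            logger.warning("model %s flagged non-converged", response)
        fits.append(fit)
    for response in DENSITY_RESPONSES:
        fits.append(fit_density_lm(net_frame, response))
    tables_txt = "\n\n".join(fit.to_text() for fit in fits)
    (out / "model_tables.txt").write_text(tables_txt + "\n")
    (out / "model_fits.json").write_text(
        json.dumps([fit.to_dict() for fit in fits], indent=2)
    )
    artifacts["model_tables"] = str(out / "model_tables.txt")
    artifacts["model_fits"] = str(out / "model_fits.json")

    ledger = effect_summary(fits)
    ledger.to_json(out / "effect_ledger.json")
    artifacts["effect_ledger"] = str(out / "effect_ledger.json")
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return artifacts
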