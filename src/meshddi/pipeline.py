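"""End-to-end orchestration: load → filter → partition → enrich → export.

A :class:`RunConfig` names the inputs (corpus, vocabulary, drug list,
optional gold labels) and every analysis knob; :func:`run_pipeline`
executes the stages in order, writes all numeric artifacts (enrichment
TSV, co-occurrence matrices with cluster orders, ROC points, pair
networks) into the output directory and returns the run summary.  Every
artifact's header carries the config hash so outputs can be traced back
to the exact configuration; the summary additionally records the seed,
group sizes and filter attrition.  Runs are deterministic apart from the
recorded wall-clock timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import numpy as np

from . import cooccur, medline, network, rocval
from .corpus import INTERACTION_TERMS, filter_by_date, filter_reviews, partition
from .enrichment import SamplingConfig, TermEnrichment
from .vocab import TermCategory, load_mesh_ascii, load_mesh_tsv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_vocabulary"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat run configuration (mirrors the key=value config-file format)."""

    drug: str
    corpus_path: str
    vocab_path: str
    drug_list_path: str | None = None
    labels_path: str | None = None
    outdir: str = "meshddi-out"
    n_resamples: int = 1000
    seed: int = 0
    alpha: float = 0.1
    min_freq: int = 5
    correction: str | None = None
    exclude_reviews: bool = False
    date_end: str | None = None  # ISO date
    interaction_terms: list[str] = field(default_factory=lambda: list(INTERACTION_TERMS))
    min_weight: int = 2
    partner_drugs: list[str] = field(default_factory=list)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file ('#' starts a comment;
        list values are comma-separated)."""
        raw: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line (expected key = value): {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            raw[key] = value
        kwargs: dict = {}
        for f in cls.__dataclass_fields__.values():
            if f.name not in raw:
                continue
            v = raw.pop(f.name)
            if f.name in ("interaction_terms", "partner_drugs"):
                kwargs[f.name] = [s.strip() for s in v.split(",") if s.strip()]
            elif f.name in ("n_resamples", "seed", "min_freq", "min_weight"):
                kwargs[f.name] = int(v)
            elif f.name == "alpha":
                kwargs[f.name] = float(v)
            elif f.name == "exclude_reviews":
                kwargs[f.name] = v.lower() in ("1", "true", "yes", "on")
            elif f.name == "correction":
                kwargs[f.name] = None if v.lower() in ("", "none") else v
            else:
                kwargs[f.name] = v
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def sampling(self) -> SamplingConfig:
        return SamplingConfig(
            n_resamples=self.n_resamples,
            seed=self.seed,
            alpha=self.alpha,
            min_freq=self.min_freq,
            correction=self.correction,
        )


def load_vocabulary(path: str | Path, drug_list_path: str | Path | None = None):
    """Load a vocabulary file, sniffing MeSH ASCII vs simplified TSV."""
    text = Path(path).read_text(encoding="utf-8")
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    vocab = load_mesh_ascii(text) if first.strip() == "*NEWRECORD" else load_mesh_tsv(text)
    if drug_list_path is not None:
        names = Path(drug_list_path).read_text(encoding="utf-8").splitlines()
        vocab.set_drug_list(names)
    return vocab


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run summary.

    Any stage failure removes the partial outputs of this run and raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = f"config={chash} seed={config.seed}"
    written: list[Path] = []
    timings: dict[str, float] = {}
    summary: dict = {"config_hash": chash, "seed": config.seed, "drug": config.drug}
    stage = "setup"

    def artifact(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        # ---- load ----------------------------------------------------
        stage = "load"
        t0 = time.perf_counter()
        articles = medline.parse_medline(Path(config.corpus_path))
        vocab = load_vocabulary(config.vocab_path, config.drug_list_path)
        summary["n_input_articles"] = len(articles)
        timings["load"] = time.perf_counter() - t0

        # ---- filters -------------------------------------------------
        stage = "filter"
        t0 = time.perf_counter()
        if config.date_end:
            cutoff = date.fromisoformat(config.date_end)
            before = len(articles)
            articles = filter_by_date(articles, cutoff)
            summary["n_dropped_by_date"] = before - len(articles)
        if config.exclude_reviews:
            before = len(articles)
            articles = filter_reviews(articles)
            summary["n_reviews_excluded"] = before - len(articles)
        timings["filter"] = time.perf_counter() - t0

        # ---- partition -----------------------------------------------
        stage = "partition"
        t0 = time.perf_counter()
        corpus = partition(articles, config.interaction_terms, drug=config.drug)
        summary["n_group_a"] = corpus.n_a
        summary["n_group_b"] = corpus.n_b
        logger.info(
            "partition: %d DDI-related (group A), %d DDI-unrelated (group B)",
            corpus.n_a, corpus.n_b,
        )
        timings["partition"] = time.perf_counter() - t0

        # ---- enrichment ----------------------------------------------
        stage = "enrich"
        t0 = time.perf_counter()
        model = TermEnrichment(corpus, vocab, config=config.sampling())
        results = model.fit()
        results.to_tsv(artifact("enrichment.tsv"), header_comment=header)
        selected = {
            cat: sorted(r.term for r in results.selected(cat))
            for cat in (TermCategory.DRUG, TermCategory.PROTEIN, TermCategory.PHENOMENA)
        }
        summary["n_candidates"] = len(results)
        summary["n_selected"] = {c.value: len(v) for c, v in selected.items()}
        timings["enrich"] = time.perf_counter() - t0

        # ---- co-occurrence matrices ----------------------------------
        stage = "cooccur"
        t0 = time.perf_counter()
        for other_cat, tag in (
            (TermCategory.PROTEIN, "protein"),
            (TermCategory.PHENOMENA, "phenomena"),
        ):
            rows = selected[TermCategory.DRUG]
            cols = selected[other_cat]
            if not rows or not cols:
                continue
            counts = cooccur.cross_cooccurrence(corpus.group_a, rows, cols)
            normalized = cooccur.normalize_rows(counts)
            row_order, col_order = cooccur.cluster_order(normalized)
            ordered = normalized[np.ix_(row_order, col_order)]
            cooccur.write_matrix_tsv(
                counts, rows, cols,
                artifact(f"cooccurrence_drug_x_{tag}_counts.tsv"), header,
            )
            cooccur.write_matrix_tsv(
                ordered,
                [rows[i] for i in row_order],
                [cols[j] for j in col_order],
                artifact(f"cooccurrence_drug_x_{tag}_normalized_ordered.tsv"), header,
            )
            with artifact(f"cooccurrence_drug_x_{tag}_orders.json").open("w") as fh:
                json.dump(
                    {"config_hash": chash, "row_order": row_order, "col_order": col_order},
                    fh, indent=2,
                )
        timings["cooccur"] = time.perf_counter() - t0

        # ---- ROC validation ------------------------------------------
        stage = "roc"
        t0 = time.perf_counter()
        if config.labels_path:
            labels = rocval.read_labels_tsv(Path(config.labels_path))
            aucs: dict[str, float | None] = {}
            for cat in (TermCategory.DRUG, TermCategory.PROTEIN, TermCategory.PHENOMENA):
                cat_results = [
                    r for r in results if r.category is cat and r.count_a > config.min_freq
                ]
                ranking = rocval.LabeledRanking.from_results(cat_results, labels)
                try:
                    points = rocval.roc_curve(ranking)
                except ValueError:
                    aucs[cat.value] = None
                    continue
                aucs[cat.value] = rocval.auc(points)
                rocval.write_roc_tsv(points, artifact(f"roc_{cat.value}.tsv"), header)
            summary["auc"] = aucs
        timings["roc"] = time.perf_counter() - t0

        # ---- pair networks -------------------------------------------
        stage = "network"
        t0 = time.perf_counter()
        for partner in config.partner_drugs:
            net = network.build_pair_network(
                corpus, partner,
                {TermCategory.PROTEIN: selected[TermCategory.PROTEIN],
                 TermCategory.PHENOMENA: selected[TermCategory.PHENOMENA]},
                min_weight=config.min_weight,
                interaction_terms=config.interaction_terms,
            )
            slug = partner.lower().replace(" ", "_")
            network.export_graph(net, "graphml", str(artifact(f"network_{slug}.graphml")))
            network.export_graph(net, "edgelist", artifact(f"network_{slug}_edges.tsv"))
            summary.setdefault("networks", {})[partner] = {
                "n_nodes": len(net.nodes), "n_edges": len(net.edges),
            }
        timings["network"] = time.perf_counter() - t0

        # ---- summary -------------------------------------------------
        stage = "summary"
        summary["timings_s"] = {k: round(v, 4) for k, v in timings.items()}
        with artifact("summary.json").open("w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
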