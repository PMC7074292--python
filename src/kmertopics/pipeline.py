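"""End-to-end orchestration: genomes -> corpus -> LDA -> trees -> report.

Runs the whole comparison with one config and writes reproducible artifacts:
corpus statistics, relative-entropy profiles, theta/phi tables, Newick trees,
cluster assignments, agreement scores and an echo of the resolved config.
Identical inputs, config and seed reproduce every output byte for byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import clustering, ffp_baseline, kmer_corpus, kselect_entropy, lda
from .genome_io import load_documents, load_manifest

logger = logging.getLogger("kmertopics")


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    manifest: str
    out_dir: str
    n_topics: int = 3
    k: int | str = "auto"  # "auto" selects by cumulative relative entropy
    cre_threshold: float = kselect_entropy.DEFAULT_THRESHOLD
    k_min: int = 3
    k_max: int = kselect_entropy.DEFAULT_K_MAX
    min_df: int | float = 10
    alpha: float | None = None
    beta: float = 0.1
    n_iter: int = 2000
    burn_in: int = 1000
    metric: str = "euclidean"
    linkage: str = "average"
    cut: int | None = None
    ffp: bool = True
    seed: int = 0

    def lda_config(self) -> lda.LdaConfig:
        return lda.LdaConfig(
            n_topics=self.n_topics,
            alpha=self.alpha,
            beta=self.beta,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            seed=self.seed,
        )


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - surfaced with stage name
            raise StageError(name, exc) from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and return the JSON-serializable run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "status": "incomplete",
    }

    docs = _stage("genome_io")(load_documents, config.manifest)
    logger.info("read %d genomes", len(docs))
    report["n_genomes"] = len(docs)
    families = {d.doc_id: d.family for d in docs}

    if config.k == "auto":
        profiles = [
            _stage("kselect_entropy")(
                kselect_entropy.cre_profile, d, config.k_min, config.k_max
            )
            for d in docs
        ]
        kselect_entropy.profiles_to_frame(profiles).to_csv(
            out / "cre_profiles.tsv", sep="\t", index=False
        )
        k = _stage("kselect_entropy")(
            kselect_entropy.select_k, profiles, config.cre_threshold
        )
    else:
        k = int(config.k)
    logger.info("word length k = %d", k)
    report["k"] = k

    tables = [_stage("kmer_corpus")(kmer_corpus.extract_kmers, d, k) for d in docs]
    corpus = _stage("kmer_corpus")(kmer_corpus.build_corpus, tables, config.min_df)
    stats = kmer_corpus.corpus_stats(tables, corpus)
    report["corpus_stats"] = dataclasses.asdict(stats)
    kmer_corpus.save_corpus(corpus, out / "corpus")
    logger.info(
        "corpus: %d/%d words kept (min_df=%d), %d tokens",
        stats.selected_vocab,
        stats.union_distinct,
        corpus.min_df,
        stats.token_sum,
    )

    model = _stage("lda")(lda.fit_lda, corpus, config.lda_config())
    lda.save_model(model, out)
    report["log_likelihood"] = lda.log_likelihood(model, corpus)

    D = _stage("clustering")(
        clustering.topic_distance_matrix, model.theta, corpus.doc_ids, config.metric
    )
    tree = _stage("clustering")(clustering.hierarchical_cluster, D, config.linkage)
    (out / "topic_tree.nwk").write_text(clustering.to_newick(tree) + "\n")

    n_cut = config.cut if config.cut is not None else config.n_topics
    labels = _stage("clustering")(clustering.cut_tree, tree, n_cut)
    score = clustering.agreement(labels, families)
    report["agreement"] = {
        "purity": score.purity,
        "adjusted_rand_index": score.adjusted_rand_index,
        "misplaced": score.misplaced,
    }
    pd.DataFrame(
        {
            "doc_id": sorted(labels),
            "cluster": [labels[i] for i in sorted(labels)],
            "family": [families[i] for i in sorted(labels)],
        }
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)

    if config.ffp:
        profiles = [
            _stage("ffp_baseline")(ffp_baseline.frequency_profile, t, corpus.vocabulary)
            for t in tables
        ]
        ftree = _stage("ffp_baseline")(ffp_baseline.ffp_tree, profiles, config.linkage)
        (out / "ffp_tree.nwk").write_text(clustering.to_newick(ftree) + "\n")
        flabels = clustering.cut_tree(ftree, n_cut)
        fscore = clustering.agreement(flabels, families)
        report["ffp_agreement"] = {
            "purity": fscore.purity,
            "adjusted_rand_index": fscore.adjusted_rand_index,
            "misplaced": fscore.misplaced,
        }

    report["status"] = "complete"
    write_report(report, out / "report.json")
    return report


def write_report(report: dict[str, Any], path: str | Path) -> None:
    """JSON report with stable key order."""
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
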