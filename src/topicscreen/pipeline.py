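"""End-to-end screening experiments.

Orchestrates the full comparison the toolkit exists for: preprocess a
labelled corpus, optionally fuse recognised multi-word terms, represent
documents as TF-IDF bags-of-words (BOW), LDA topic proportions (TPC) or
term-enriched topic proportions (TE), train imbalance-weighted SVMs with
linear/RBF/polynomial kernels on a stratified half, evaluate on the held-out
half, average over seeds, and summarise representations across corpora with
Friedman mean ranks.

Topic features are transductive by default: the topic model is fitted on the
full unlabelled corpus before splitting, and each document's fitted
proportions are its features.  ``transductive=False`` instead fits the model
on the training half only and folds the test half in, which avoids any use
of test-set text during unsupervised fitting.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import corpus as cio
from . import terms as tr
from .classify import ImbalanceWeightedSVC
from .corpus import Corpus, FeatureMatrix
from .errors import ValidationError
from .lda import LDAConfig, LatentDirichletAllocationGibbs, top_terms
from .metrics import MetricSet, evaluate_scores, friedman_test

logger = logging.getLogger(__name__)

REPRESENTATIONS = ("BOW", "TPC", "TE")
KERNELS = ("linear", "rbf", "poly")
METRIC_NAMES = ("precision", "recall", "f1", "accuracy", "roc_auc", "prc_auc")


@dataclass
class RunConfig:
    """One experiment: corpora, feature representations, kernels, seeds."""

    corpora: dict[str, Corpus] = dc_field(default_factory=dict)
    representations: tuple[str, ...] = REPRESENTATIONS
    kernels: tuple[str, ...] = KERNELS
    n_topics: int = 30
    lda_iterations: int = 300
    lda_burn_in: int = 100
    split_fraction: float = 0.5
    seeds: tuple[int, ...] = (0, 1, 2)
    transductive: bool = True
    output_dir: str | Path | None = None

    def __post_init__(self):
        if not self.representations or not self.kernels:
            raise ValidationError("representation and kernel sets must be nonempty")
        if not self.seeds:
            raise ValidationError("seeds must be nonempty")
        bad = set(self.representations) - set(REPRESENTATIONS)
        if bad:
            raise ValidationError(f"unknown representations {sorted(bad)}")
        bad = set(self.kernels) - set(KERNELS)
        if bad:
            raise ValidationError(f"unknown kernels {sorted(bad)}")

    def lda_config(self, seed: int) -> LDAConfig:
        return LDAConfig(
            n_topics=self.n_topics, iterations=self.lda_iterations,
            burn_in=self.lda_burn_in, thin=max(1, self.lda_iterations // 20),
            seed=seed,
        )


def _prepared(corpus: Corpus) -> Corpus:
    """Preprocess if needed (documents without token streams)."""
    if all(d.tokens for d in corpus.documents if d.text):
        if not corpus.vocabulary:
            corpus.build_vocabulary()
        return corpus
    return cio.preprocess_corpus(corpus)


def term_enrich(corpus: Corpus, lexicon: tr.TermLexicon | None = None) -> Corpus:
    """Fuse recognised multi-word terms into single tokens corpus-wide."""
    if lexicon is None:
        lexicon = tr.extract_terms([d.tokens for d in corpus])
    from dataclasses import replace

    out = Corpus(
        documents=[
            replace(d, tokens=tr.locate_terms(d.tokens, lexicon))
            for d in corpus
        ]
    )
    out.build_vocabulary()
    return out


def build_features(
    corpus: Corpus,
    representation: str,
    lda_config: LDAConfig | None = None,
    lexicon: tr.TermLexicon | None = None,
) -> FeatureMatrix:
    """Feature matrix for every document of an already-preprocessed corpus."""
    corpus = _prepared(corpus)
    if representation == "BOW":
        return cio.tfidf_vectorize(cio.remove_hapax(corpus))
    if representation in ("TPC", "TE"):
        if representation == "TE":
            corpus = term_enrich(corpus, lexicon)
        corpus = cio.remove_hapax(corpus)
        cfg = lda_config or LDAConfig(n_topics=30, iterations=300, burn_in=100)
        model = LatentDirichletAllocationGibbs(
            n_topics=cfg.n_topics, alpha=cfg.alpha, beta=cfg.beta,
            n_iter=cfg.iterations, burn_in=cfg.burn_in, thin=cfg.thin,
            random_state=cfg.seed,
        ).fit(corpus)
        return FeatureMatrix(
            X=model.doc_topic_, y=corpus.labels(), feature_kind=representation,
            doc_ids=[d.doc_id for d in corpus],
        )
    raise ValidationError(f"unknown representation {representation!r}")


def _split_rows(
    corpus: Corpus, features: FeatureMatrix, fraction: float, seed: int
):
    train_c, test_c = cio.stratified_split(corpus, fraction=fraction, seed=seed)
    pos = {doc_id: i for i, doc_id in enumerate(features.doc_ids)}
    tr_idx = np.array([pos[d.doc_id] for d in train_c])
    te_idx = np.array([pos[d.doc_id] for d in test_c])
    return tr_idx, te_idx


def evaluate_cell(
    corpus: Corpus,
    representation: str,
    kernel: str,
    lda_config: LDAConfig | None = None,
    split_fraction: float = 0.5,
    seed: int = 0,
    transductive: bool = True,
    lexicon: tr.TermLexicon | None = None,
) -> MetricSet:
    """Split, train and evaluate one (representation, kernel) cell."""
    corpus = _prepared(corpus)
    if transductive or representation == "BOW":
        features = build_features(corpus, representation, lda_config, lexicon)
        tr_idx, te_idx = _split_rows(corpus, features, split_fraction, seed)
        X, y = features.X, features.y
        X_tr, y_tr = X[tr_idx], y[tr_idx]
        X_te, y_te = X[te_idx], y[te_idx]
    else:
        train_c, test_c = cio.stratified_split(
            corpus, fraction=split_fraction, seed=seed
        )
        if representation == "TE":
            lexicon = lexicon or tr.extract_terms([d.tokens for d in train_c])
            train_c = term_enrich(train_c, lexicon)
            test_c = term_enrich(test_c, lexicon)
        train_c = cio.remove_hapax(train_c)
        cfg = lda_config or LDAConfig(n_topics=30, iterations=300, burn_in=100)
        model = LatentDirichletAllocationGibbs(
            n_topics=cfg.n_topics, alpha=cfg.alpha, beta=cfg.beta,
            n_iter=cfg.iterations, burn_in=cfg.burn_in, thin=cfg.thin,
            random_state=cfg.seed,
        ).fit(train_c)
        X_tr, y_tr = model.doc_topic_, train_c.labels()
        X_te, y_te = model.transform(test_c), test_c.labels()
    clf = ImbalanceWeightedSVC(kernel=kernel).fit(X_tr, y_tr)
    scores = clf.decision_function(X_te)
    return evaluate_scores(y_te, scores)


def evaluate_topic_cell(
    corpus: Corpus,
    n_topics: int,
    kernel: str = "linear",
    base_config: LDAConfig | None = None,
    split_fraction: float = 0.5,
    seed: int = 0,
) -> MetricSet:
    """One row of a topic-density sweep: TPC features at the given K."""
    if base_config is not None:
        cfg = LDAConfig(
            n_topics=n_topics, alpha=base_config.alpha, beta=base_config.beta,
            iterations=base_config.iterations, burn_in=base_config.burn_in,
            thin=base_config.thin, seed=base_config.seed,
        )
    else:
        cfg = LDAConfig(n_topics=n_topics, iterations=300, burn_in=100, seed=seed)
    return evaluate_cell(
        corpus, "TPC", kernel, lda_config=cfg,
        split_fraction=split_fraction, seed=seed,
    )


def comparison_report(
    corpora: dict[str, Corpus],
    representations: Sequence[str] = REPRESENTATIONS,
    kernels: Sequence[str] = KERNELS,
    config: RunConfig | None = None,
) -> dict:
    """Full metric grid plus Friedman summaries and recall-ordered rankings.

    Returns a dict with ``grid`` (tidy DataFrame: corpus x representation x
    kernel x metric, seed-averaged), ``friedman`` (per metric and kernel,
    mean ranks over representations across corpora; requires >= 2 corpora
    and >= 3 representations), and ``rankings`` (kernel and representation
    orderings by mean recall).
    """
    config = config or RunConfig(
        corpora=dict(corpora),
        representations=tuple(representations),
        kernels=tuple(kernels),
    )
    rows = []
    for cname, corpus in corpora.items():
        corpus = _prepared(corpus)
        for rep in representations:
            for kernel in kernels:
                per_seed = []
                cell_error = ""
                for seed in config.seeds:
                    try:
                        t0 = time.perf_counter()
                        ms = evaluate_cell(
                            corpus, rep, kernel,
                            lda_config=config.lda_config(seed),
                            split_fraction=config.split_fraction,
                            seed=seed,
                            transductive=config.transductive,
                        )
                        logger.info(
                            "%s/%s/%s seed=%d done in %.1fs",
                            cname, rep, kernel, seed, time.perf_counter() - t0,
                        )
                        per_seed.append(ms.as_dict())
                    except Exception as exc:  # noqa: BLE001 - flag, continue
                        cell_error = str(exc)
                        logger.warning(
                            "cell %s/%s/%s seed=%d failed: %s",
                            cname, rep, kernel, seed, exc,
                        )
                row = {"corpus": cname, "representation": rep, "kernel": kernel,
                       "error": cell_error}
                if per_seed:
                    for m in METRIC_NAMES:
                        row[m] = float(np.mean([d[m] for d in per_seed]))
                rows.append(row)
    grid = pd.DataFrame(rows)

    friedman: dict[str, dict] = {}
    reps = list(representations)
    if len(corpora) >= 2 and len(reps) >= 3:
        for kernel in kernels:
            for metric in METRIC_NAMES:
                sub = grid[(grid.kernel == kernel) & (grid.error == "")]
                table = sub.pivot(index="corpus", columns="representation",
                                  values=metric)
                if table.isna().any().any() or table.shape[0] < 2:
                    continue
                table = table[reps]
                res = friedman_test(table.to_numpy(), group_names=reps)
                friedman[f"{metric}/{kernel}"] = {
                    "groups": reps,
                    "mean_ranks": [float(r) for r in res.mean_ranks],
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                }

    rankings = {}
    ok = grid[grid.error == ""]
    if "recall" in ok.columns and not ok.empty:
        by_kernel = ok.groupby("kernel")["recall"].mean().sort_values(
            ascending=False
        )
        rankings["kernels_by_recall"] = " > ".join(
            k.upper() for k in by_kernel.index
        )
        by_rep = ok.groupby("representation")["recall"].mean().sort_values(
            ascending=False
        )
        rankings["representations_by_recall"] = " > ".join(by_rep.index)

    return {"grid": grid, "friedman": friedman, "rankings": rankings}


def run_experiment(config: RunConfig) -> dict:
    """Execute a configured experiment and (optionally) write its bundle.

    Writes, under ``config.output_dir``: the seed-averaged metric grid as
    TSV, the Friedman block and rankings as JSON, top-term listings for one
    fitted topic model per corpus, and a timestamped log.  Returns the
    report dict of :func:`comparison_report` augmented with topic listings.
    """
    if not config.corpora:
        raise ValidationError("config lists no corpora")
    t_start = time.perf_counter()
    report = comparison_report(
        config.corpora, config.representations, config.kernels, config
    )

    topics: dict[str, list[list[str]]] = {}
    wants_topics = {"TPC", "TE"} & set(config.representations)
    if wants_topics:
        for cname, corpus in config.corpora.items():
            corpus = _prepared(corpus)
            if "TE" in config.representations:
                corpus = term_enrich(corpus)
            corpus = cio.remove_hapax(corpus)
            cfg = config.lda_config(config.seeds[0])
            model = LatentDirichletAllocationGibbs(
                n_topics=cfg.n_topics, alpha=cfg.alpha, beta=cfg.beta,
                n_iter=cfg.iterations, burn_in=cfg.burn_in, thin=cfg.thin,
                random_state=cfg.seed,
            ).fit(corpus)
            topics[cname] = [
                [t.display for t in top_terms(model, k, 10)]
                for k in range(min(cfg.n_topics, 10))
            ]
    report["topics"] = topics
    report["elapsed_seconds"] = time.perf_counter() - t_start

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report["grid"].to_csv(out / "grid.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "friedman": report["friedman"],
                    "rankings": report["rankings"],
                    "elapsed_seconds": report["elapsed_seconds"],
                    "config": {
                        "representations": list(config.representations),
                        "kernels": list(config.kernels),
                        "n_topics": config.n_topics,
                        "split_fraction": config.split_fraction,
                        "seeds": list(config.seeds),
                        "transductive": config.transductive,
                    },
                },
                fh, indent=2,
            )
        with open(out / "topics.txt", "w", encoding="utf-8") as fh:
            for cname, listing in topics.items():
                fh.write(f"# {cname}\n")
                for k, words in enumerate(listing):
                    fh.write(f"topic {k}: {', '.join(words)}\n")
    return report
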