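"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Each document m mixes K topics through a Dirichlet-distributed proportion
vector theta_m, and each topic k is a Dirichlet-distributed distribution
phi_k over the vocabulary; every token draws a topic from theta_m and then a
word from phi_{z}.  After integrating theta and phi out analytically, the
full conditional for a single token assignment is

    p(z_i = k | z_-i, w)  ∝  (n_dk + alpha) * (n_kw + beta) / (n_k + V*beta)

which the sampler iterates over all token positions.  Point estimates are
averaged over thinned post-burn-in sweeps:

    theta[d, k] = (n_dk + alpha) / (N_d + K*alpha)
    phi[k, w]   = (n_kw + beta) / (n_k + V*beta)

The resulting K-dimensional topic proportions are the document features used
for screening classification; held-out documents are folded in by sampling
their assignments with phi held fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin
import scipy.sparse as sp

from .corpus import Corpus
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: topic-count grid for density sweeps: 2 to 100 in steps of ~10, then
#: coarser steps up to 500
DEFAULT_K_GRID = (2, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 150, 200, 300, 500)


@dataclass
class LDAConfig:
    """Sampler configuration: topic count, symmetric priors and schedule.

    ``alpha=None`` resolves to max(1/K, 0.1); priors are symmetric so every
    topic is a priori exchangeable.
    """

    n_topics: int
    alpha: float | None = None
    beta: float = 0.01
    iterations: int = 1000
    burn_in: int = 200
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_topics < 1:
            raise ValidationError("n_topics must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        if self.beta <= 0:
            raise ValidationError("beta must be positive")
        if not self.iterations > self.burn_in >= 0:
            raise ValidationError("need iterations > burn_in >= 0")

    @property
    def resolved_alpha(self) -> float:
        return self.alpha if self.alpha is not None else max(1.0 / self.n_topics, 0.1)


@dataclass
class GibbsState:
    """Token-level topic assignments and the count tables they induce."""

    z: np.ndarray            # topic per token position
    doc_of: np.ndarray       # document index per token position
    word_of: np.ndarray      # word index per token position
    ndk: np.ndarray          # documents x topics
    nkw: np.ndarray          # topics x vocabulary
    nk: np.ndarray           # per-topic totals


@njit(cache=True)
def _gibbs_sweep(w, d, z, ndk, nkw, nk, alpha, beta, u, probs, marg, collect):
    K, V = nkw.shape
    for i in range(w.shape[0]):
        wi = w[i]
        di = d[i]
        zi = z[i]
        ndk[di, zi] -= 1
        nkw[zi, wi] -= 1
        nk[zi] -= 1
        total = 0.0
        for k in range(K):
            p = (ndk[di, k] + alpha) * (nkw[k, wi] + beta) / (nk[k] + V * beta)
            probs[k] = p
            total += p
        if collect:
            # Rao-Blackwellised marginal: accumulate the full conditional
            for k in range(K):
                marg[i, k] += probs[k] / total
        r = u[i] * total
        acc = 0.0
        knew = K - 1
        for k in range(K):
            acc += probs[k]
            if r < acc:
                knew = k
                break
        z[i] = knew
        ndk[di, knew] += 1
        nkw[knew, wi] += 1
        nk[knew] += 1


@njit(cache=True)
def _foldin_sweep(w, z, ndk_row, phi, alpha, u, probs):
    K = phi.shape[0]
    for i in range(w.shape[0]):
        wi = w[i]
        zi = z[i]
        ndk_row[zi] -= 1
        total = 0.0
        for k in range(K):
            p = (ndk_row[k] + alpha) * phi[k, wi]
            probs[k] = p
            total += p
        r = u[i] * total
        acc = 0.0
        knew = K - 1
        for k in range(K):
            acc += probs[k]
            if r < acc:
                knew = k
                break
        z[i] = knew
        ndk_row[knew] += 1


class LatentDirichletAllocationGibbs(BaseEstimator, TransformerMixin):
    """LDA topic model fitted by collapsed Gibbs sampling.

    Parameters
    ----------
    n_topics : int
        Number of topics K (the "topic density").
    alpha : float or None
        Symmetric document-topic concentration; ``None`` -> max(1/K, 0.1).
    beta : float
        Symmetric topic-word concentration.
    n_iter, burn_in, thin : int
        Total Gibbs sweeps, sweeps discarded, and spacing of the sweeps
        averaged into the point estimates.
    random_state : int
        Seed for the sampler; identical seeds reproduce the fit bit-for-bit.
    collect_z_stats : bool
        When true, estimate per-position topic marginals over the sampled
        sweeps (``z_marginal_``, Rao-Blackwellised: the full conditional of
        each position is averaged rather than its sampled one-hot draw) for
        diagnostics against exact enumeration.

    Attributes
    ----------
    components_ : ndarray (K, V)
        Topic-word probabilities phi, rows summing to one.
    doc_topic_ : ndarray (D, K)
        Topic proportions theta of the training documents.
    vocabulary_ : dict
        Token -> column index (when fitted from token streams).
    state_ : GibbsState
        Final assignments and count tables.
    """

    def __init__(
        self,
        n_topics: int = 10,
        alpha: float | None = None,
        beta: float = 0.01,
        n_iter: int = 1000,
        burn_in: int = 200,
        thin: int = 10,
        random_state: int = 0,
        collect_z_stats: bool = False,
    ):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.random_state = random_state
        self.collect_z_stats = collect_z_stats

    # -- helpers ----------------------------------------------------------

    def _config(self) -> LDAConfig:
        return LDAConfig(
            n_topics=self.n_topics, alpha=self.alpha, beta=self.beta,
            iterations=self.n_iter, burn_in=self.burn_in, thin=self.thin,
            seed=self.random_state,
        )

    def _encode(self, X) -> list[list[int]]:
        """Normalise input to per-document lists of word ids."""
        if isinstance(X, Corpus):
            if not X.vocabulary:
                X.build_vocabulary()
            self.vocabulary_ = dict(X.vocabulary)
            return [[self.vocabulary_[t] for t in d.tokens] for d in X]
        if sp.issparse(X) or isinstance(X, np.ndarray):
            M = sp.csr_matrix(X)
            self.vocabulary_ = None
            docs = []
            for i in range(M.shape[0]):
                row = M.getrow(i)
                toks: list[int] = []
                for j, c in zip(row.indices, row.data):
                    toks.extend([int(j)] * int(round(c)))
                docs.append(toks)
            return docs
        # sequences of string tokens
        docs_tok = [list(doc) for doc in X]
        vocab = sorted({t for doc in docs_tok for t in doc})
        self.vocabulary_ = {t: i for i, t in enumerate(vocab)}
        return [[self.vocabulary_[t] for t in doc] for doc in docs_tok]

    # -- estimation -------------------------------------------------------

    def fit(self, X, y=None):
        cfg = self._config()
        docs = self._encode(X)
        if self.vocabulary_ is not None:
            V = len(self.vocabulary_)
        else:
            V = max((max(doc) for doc in docs if doc), default=-1) + 1
        if V == 0:
            raise ValidationError("cannot fit a topic model on an empty vocabulary")
        D, K = len(docs), cfg.n_topics
        alpha, beta = cfg.resolved_alpha, cfg.beta

        empty = [i for i, doc in enumerate(docs) if not doc]
        if empty:
            logger.warning(
                "%d document(s) have no tokens; excluded from fitting, "
                "assigned uniform topic proportions", len(empty),
            )
        d_idx = np.array(
            [i for i, doc in enumerate(docs) for _ in doc], dtype=np.int64
        )
        w_idx = np.array([w for doc in docs for w in doc], dtype=np.int64)
        N = w_idx.shape[0]
        if N == 0:
            raise ValidationError("corpus contains no tokens")

        rng = np.random.default_rng(self.random_state)
        z = rng.integers(0, K, size=N).astype(np.int64)
        ndk = np.zeros((D, K), dtype=np.int64)
        nkw = np.zeros((K, V), dtype=np.int64)
        nk = np.zeros(K, dtype=np.int64)
        np.add.at(ndk, (d_idx, z), 1)
        np.add.at(nkw, (z, w_idx), 1)
        np.add.at(nk, z, 1)

        doc_len = np.array([len(doc) for doc in docs], dtype=float)
        probs = np.empty(K, dtype=np.float64)
        theta_sum = np.zeros((D, K))
        phi_sum = np.zeros((K, V))
        n_samples = 0
        zmarg = np.zeros((N, K), dtype=np.float64)
        n_marg = 0

        for sweep in range(cfg.iterations):
            u = rng.random(N)
            sample_now = (
                sweep >= cfg.burn_in and (sweep - cfg.burn_in) % cfg.thin == 0
            )
            collect = self.collect_z_stats and sample_now
            _gibbs_sweep(w_idx, d_idx, z, ndk, nkw, nk, alpha, beta, u, probs,
                         zmarg, collect)
            if collect:
                n_marg += 1
            if sample_now:
                theta_sum += (ndk + alpha) / (
                    doc_len[:, None] + K * alpha
                )
                phi_sum += (nkw + beta) / (nk[:, None] + V * beta)
                n_samples += 1

        theta = theta_sum / n_samples
        theta[empty, :] = 1.0 / K
        self.components_ = phi_sum / n_samples
        self.doc_topic_ = theta
        self.state_ = GibbsState(
            z=z, doc_of=d_idx, word_of=w_idx, ndk=ndk, nkw=nkw, nk=nk
        )
        self.n_samples_ = n_samples
        if self.collect_z_stats:
            self.z_marginal_ = zmarg / n_marg
        return self

    def transform(self, X) -> np.ndarray:
        """Fold-in topic proportions for (possibly unseen) documents."""
        docs = self._encode_for_inference(X)
        ss = np.random.SeedSequence(self.random_state)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(docs))]
        return np.vstack(
            [self._infer_one(doc, seed=s) for doc, s in zip(docs, seeds)]
        )

    def fit_transform(self, X, y=None):
        """Fit, then return the training documents' averaged proportions."""
        return self.fit(X).doc_topic_

    def _encode_for_inference(self, X) -> list[list[int]]:
        if isinstance(X, Corpus):
            docs_tok = [d.tokens for d in X]
        elif sp.issparse(X) or isinstance(X, np.ndarray):
            M = sp.csr_matrix(X)
            if M.shape[1] != self.components_.shape[1]:
                raise ValidationError(
                    f"feature count {M.shape[1]} != vocabulary size "
                    f"{self.components_.shape[1]}"
                )
            return [
                [int(j) for j, c in zip(M.getrow(i).indices, M.getrow(i).data)
                 for _ in range(int(round(c)))]
                for i in range(M.shape[0])
            ]
        else:
            docs_tok = [list(doc) for doc in X]
        if self.vocabulary_ is None:
            raise ValidationError(
                "model was fitted on count matrices; pass count matrices"
            )
        # unseen tokens are skipped: they carry no evidence about the topics
        return [
            [self.vocabulary_[t] for t in doc if t in self.vocabulary_]
            for doc in docs_tok
        ]

    def _infer_one(
        self, word_ids: Sequence[int], iterations: int = 200,
        burn_in: int = 50, thin: int = 5, seed: int = 0,
    ) -> np.ndarray:
        K = self.components_.shape[0]
        alpha = self._config().resolved_alpha
        w = np.asarray(list(word_ids), dtype=np.int64)
        if w.size == 0:
            return np.full(K, 1.0 / K)
        rng = np.random.default_rng(seed)
        z = rng.integers(0, K, size=w.size).astype(np.int64)
        ndk_row = np.bincount(z, minlength=K).astype(np.int64)
        probs = np.empty(K)
        theta_sum = np.zeros(K)
        n_samples = 0
        phi = self.components_
        for sweep in range(iterations):
            u = rng.random(w.size)
            _foldin_sweep(w, z, ndk_row, phi, alpha, u, probs)
            if sweep >= burn_in and (sweep - burn_in) % thin == 0:
                theta_sum += (ndk_row + alpha) / (w.size + K * alpha)
                n_samples += 1
        return theta_sum / n_samples


# ---------------------------------------------------------------------------
# functional wrappers


def fit_lda(corpus: Corpus, config: LDAConfig):
    """Fit LDA on a corpus; returns (model, per-document theta, final state)."""
    model = LatentDirichletAllocationGibbs(
        n_topics=config.n_topics, alpha=config.alpha, beta=config.beta,
        n_iter=config.iterations, burn_in=config.burn_in, thin=config.thin,
        random_state=config.seed,
    ).fit(corpus)
    return model, model.doc_topic_, model.state_


def infer_theta(
    model: LatentDirichletAllocationGibbs,
    tokens: Sequence[str],
    iterations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Fold-in inference of one document's topic proportions."""
    if model.vocabulary_ is None:
        raise ValidationError("model has no vocabulary; fit from token streams")
    ids = [model.vocabulary_[t] for t in tokens if t in model.vocabulary_]
    return model._infer_one(ids, iterations=iterations, seed=seed)


def _dirichlet_logpdf(x: np.ndarray, conc: float) -> float:
    if np.any(x <= 0):
        return -np.inf
    K = x.shape[0]
    return float(gammaln(K * conc) - K * gammaln(conc) + (conc - 1) * np.log(x).sum())


def log_joint(
    state: GibbsState,
    thetas: np.ndarray,
    model_phi: np.ndarray,
    config: LDAConfig,
) -> float:
    """Log of the complete-data likelihood of the corpus.

    Sums, over every token, log phi[z, w] + log theta[d, z]; adds the log
    Dirichlet prior density of every document's theta and of every topic's
    phi row.  A zero probability anywhere yields -inf rather than an error.
    """
    K, V = model_phi.shape
    if thetas.shape[1] != K:
        raise ValidationError("theta/phi topic dimensions disagree")
    alpha, beta = config.resolved_alpha, config.beta
    phi_tok = model_phi[state.z, state.word_of]
    theta_tok = thetas[state.doc_of, state.z]
    if np.any(phi_tok <= 0) or np.any(theta_tok <= 0):
        return -np.inf
    total = float(np.log(phi_tok).sum() + np.log(theta_tok).sum())
    for d in range(thetas.shape[0]):
        total += _dirichlet_logpdf(thetas[d], alpha)
    for k in range(K):
        total += _dirichlet_logpdf(model_phi[k], beta)
    return total


def greedy_topic_match(phi_true: np.ndarray, phi_est: np.ndarray):
    """Greedily pair estimated topics with true topics by maximal overlap.

    Overlap between two word distributions is sum(min(p, q)) = 1 - TV.
    Returns (pairs, tv) where pairs[i] = (true_topic, matched_estimate) and
    tv[i] is the total-variation distance of that pair.  Used by parameter-
    recovery experiments on synthetic corpora.
    """
    if phi_true.shape != phi_est.shape:
        raise ValidationError("phi tables must share a shape to be matched")
    K = phi_true.shape[0]
    overlap = np.array(
        [[np.minimum(phi_true[i], phi_est[j]).sum() for j in range(K)]
         for i in range(K)]
    )
    pairs, tvs = [], []
    free_true, free_est = set(range(K)), set(range(K))
    for _ in range(K):
        best = max(
            ((i, j) for i in free_true for j in free_est),
            key=lambda ij: overlap[ij],
        )
        pairs.append(best)
        tvs.append(1.0 - overlap[best])
        free_true.discard(best[0])
        free_est.discard(best[1])
    return pairs, np.array(tvs)


@dataclass
class TopicTerm:
    """One entry of a rendered topic listing."""

    token: str
    display: str
    probability: float
    multiword: bool


def top_terms(
    model: LatentDirichletAllocationGibbs, topic: int, n: int
) -> list[TopicTerm]:
    """The ``n`` most probable tokens of a topic, fused terms rendered with
    spaces and flagged as multi-word."""
    K, V = model.components_.shape
    if not 0 <= topic < K:
        raise ValidationError(f"topic index {topic} outside 0..{K - 1}")
    if model.vocabulary_ is None:
        raise ValidationError("model has no vocabulary to render")
    inv = {i: t for t, i in model.vocabulary_.items()}
    row = model.components_[topic]
    order = sorted(range(V), key=lambda j: (-row[j], inv[j]))
    out = []
    for j in order[: max(n, 0)]:
        tok = inv[j]
        out.append(
            TopicTerm(
                token=tok,
                display=tok.replace("_", " "),
                probability=float(row[j]),
                multiword="_" in tok,
            )
        )
    return out


def topic_density_sweep(
    corpus: Corpus,
    K_grid: Sequence[int] = DEFAULT_K_GRID,
    base_config: LDAConfig | None = None,
    kernel: str = "linear",
    split_fraction: float = 0.5,
    split_seed: int = 0,
):
    """Fit LDA at each topic count, train a weighted classifier on the topic
    features and evaluate on the held-out half; one metric row per K.

    Failures for an individual K are flagged in the output row and the sweep
    continues.  Returns a pandas DataFrame.
    """
    import pandas as pd

    from .pipeline import evaluate_topic_cell

    if not K_grid:
        raise ValidationError("K_grid must be nonempty")
    rows = []
    for K in K_grid:
        try:
            metrics = evaluate_topic_cell(
                corpus, n_topics=K, kernel=kernel, base_config=base_config,
                split_fraction=split_fraction, seed=split_seed,
            )
            rows.append({"topic_density": K, "error": "", **metrics.as_dict()})
        except Exception as exc:  # noqa: BLE001 - sweep must complete
            rows.append({"topic_density": K, "error": str(exc)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialisation


def save_model(model: LatentDirichletAllocationGibbs, directory: str | Path) -> None:
    """Write vocabulary TSV, phi TSV (topic per row) and config text."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if model.vocabulary_ is None:
        raise ValidationError("only vocabulary-bearing models are serialisable")
    with open(directory / "vocabulary.tsv", "w", encoding="utf-8") as fh:
        for tok, idx in sorted(model.vocabulary_.items(), key=lambda kv: kv[1]):
            fh.write(f"{tok}\t{idx}\n")
    np.savetxt(directory / "phi.tsv", model.components_, delimiter="\t", fmt="%.12g")
    cfg = model.get_params()
    with open(directory / "config.txt", "w", encoding="utf-8") as fh:
        for key, value in sorted(cfg.items()):
            fh.write(f"{key}={value}\n")


def load_model(directory: str | Path) -> LatentDirichletAllocationGibbs:
    directory = Path(directory)
    params: dict = {}
    for line in (directory / "config.txt").read_text().splitlines():
        key, _, value = line.partition("=")
        if value == "None":
            params[key] = None
        elif value in ("True", "False"):
            params[key] = value == "True"
        else:
            try:
                params[key] = int(value)
            except ValueError:
                params[key] = float(value)
    model = LatentDirichletAllocationGibbs(**params)
    model.components_ = np.atleast_2d(
        np.loadtxt(directory / "phi.tsv", delimiter="\t")
    )
    vocab = {}
    for line in (directory / "vocabulary.tsv").read_text("utf-8").splitlines():
        tok, _, idx = line.partition("\t")
        vocab[tok] = int(idx)
    model.vocabulary_ = vocab
    return model
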