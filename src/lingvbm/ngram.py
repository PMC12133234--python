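"""N-gram language models and cross-validated perplexity for interview transcripts.

Perplexity is the exponentiated per-token cross-entropy of a held-out word
sequence under a language model, ``PP = exp(-(1/N) * sum_i ln p(w_i | ctx_i))``.
Lower perplexity means more predictable speech.  Two model orders are
supported: unigram (order 1, each word scored without context) and bigram
(order 2, each word scored given the immediately preceding word).

Per-participant scores are obtained by leave-one-participant-out
cross-validation: the model scoring a participant's transcript is trained on
every other participant's transcript, so a participant's own idiosyncrasies
never leak into their training data.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "UNK",
    "BOS",
    "EOS",
    "Transcript",
    "NGramModel",
    "PerplexityScores",
    "tokenize",
    "fit_ngram",
    "perplexity",
    "loocv_perplexity",
    "read_transcripts_jsonl",
    "write_transcripts_jsonl",
    "read_transcript_dir",
    "scores_to_frame",
]

UNK = "<unk>"
BOS = "<s>"
EOS = "</s>"

_WORD_RE = re.compile(r"\w+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lower-case, strip punctuation and split on whitespace.

    Tokens are maximal runs of word characters; everything else is a
    separator.  ``"Die Schule, die Schule!"`` -> ``["die", "schule", "die",
    "schule"]``.  Text without word characters yields an empty list.
    """
    return _WORD_RE.findall(text.lower())


@dataclass(frozen=True)
class Transcript:
    """An ordered token sequence owned by one participant."""

    participant_id: str
    tokens: tuple[str, ...]

    def __init__(self, participant_id: str, tokens: Sequence[str]):
        object.__setattr__(self, "participant_id", str(participant_id))
        object.__setattr__(self, "tokens", tuple(tokens))
        if not self.tokens:
            raise ValueError(f"transcript {participant_id!r} has no tokens")
        if any(t == "" for t in self.tokens):
            raise ValueError(f"transcript {participant_id!r} contains empty tokens")


@dataclass
class NGramModel:
    """Add-k smoothed n-gram model of order 1 or 2.

    ``vocabulary`` is the mapped training vocabulary: training types with
    frequency >= ``min_count``, plus ``<unk>`` whenever the mapping actually
    replaced some training token.  Probabilities are normalized over that
    vocabulary (order 2: vocabulary plus the end-of-sequence marker); a token
    outside it scores ``k / (N + k*V)``, the mass of one additional unseen
    type, so cross-validated evaluation never meets a zero probability.
    """

    order: int
    k: float
    min_count: int
    vocabulary: frozenset[str]
    counts: dict  # order 1: {token: count}; order 2: {(prev, tok): count}
    context_totals: dict  # order 1: {(): N}; order 2: {prev: count}

    @property
    def _n_outcomes(self) -> int:
        if self.order == 1:
            return len(self.vocabulary)
        return len(self.vocabulary) + 1  # EOS is a predictable outcome

    def map_token(self, token: str) -> str:
        return token if token in self.vocabulary else UNK

    def prob(self, token: str, context: str | None = None) -> float:
        """Smoothed probability of ``token`` (mapped to <unk> if OOV).

        For order 2, ``context`` is the previous token (``<s>`` at the
        sequence start), itself mapped to <unk> when out of vocabulary.
        """
        v = self._n_outcomes
        if self.order == 1:
            tok = self.map_token(token)
            n = self.context_totals[()]
            c = self.counts.get(tok, 0)
            return (c + self.k) / (n + self.k * v)
        if context is None:
            raise ValueError("order-2 model requires a context token")
        tok = token if (token == EOS or token in self.vocabulary) else UNK
        ctx = context if (context == BOS or context in self.vocabulary) else UNK
        n = self.context_totals.get(ctx, 0)
        c = self.counts.get((ctx, tok), 0)
        return (c + self.k) / (n + self.k * v)

    def sequence_logprobs(self, tokens: Sequence[str]) -> list[float]:
        """Natural-log probabilities of each scored position.

        Order 1 scores every token (N positions).  Order 2 wraps the
        sequence in <s>...</s> and scores every position after <s>,
        including </s> (N + 1 positions).
        """
        if not tokens:
            raise ValueError("cannot score an empty transcript")
        if self.order == 1:
            return [math.log(self.prob(t)) for t in tokens]
        seq = [BOS, *tokens, EOS]
        return [
            math.log(self.prob(cur, prev)) for prev, cur in zip(seq, seq[1:])
        ]


def fit_ngram(
    training: Sequence[Transcript],
    order: int,
    k: float = 1.0,
    min_count: int = 1,
) -> NGramModel:
    """Fit an add-k smoothed model of the given order on a training corpus.

    Types occurring fewer than ``min_count`` times across the training corpus
    are replaced by ``<unk>`` before counting; for order 2 each transcript is
    wrapped in ``<s> ... </s>``.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    if not training:
        raise ValueError("empty training corpus")
    if k <= 0:
        raise ValueError(f"additive smoothing constant must be > 0, got {k}")

    raw = Counter()
    for tr in training:
        raw.update(tr.tokens)
    vocab = {w for w, c in raw.items() if c >= min_count}
    if len(vocab) < len(raw):
        vocab.add(UNK)
    vocab_f = frozenset(vocab)

    def _map(w: str) -> str:
        return w if w in vocab_f else UNK

    if order == 1:
        counts: Counter = Counter()
        for tr in training:
            counts.update(_map(w) for w in tr.tokens)
        totals = {(): sum(counts.values())}
        return NGramModel(1, k, min_count, vocab_f, dict(counts), totals)

    pair_counts: Counter = Counter()
    ctx_totals: Counter = Counter()
    for tr in training:
        seq = [BOS, *(_map(w) for w in tr.tokens), EOS]
        for prev, cur in zip(seq, seq[1:]):
            pair_counts[(prev, cur)] += 1
            ctx_totals[prev] += 1
    return NGramModel(2, k, min_count, vocab_f, dict(pair_counts), dict(ctx_totals))


def perplexity(model: NGramModel, transcript: Transcript) -> float:
    """Cross-entropy perplexity of one transcript under a fitted model.

    Base-invariant: internally computed with natural logs, but identical for
    any log base b since ``PP = b**H_b``.
    """
    logps = model.sequence_logprobs(transcript.tokens)
    h = -sum(logps) / len(logps)
    return math.exp(h)


@dataclass(frozen=True)
class PerplexityScores:
    """Per-participant cross-validated perplexities."""

    participant_id: str
    pp_1g: float
    pp_2g: float
    n_tokens_scored: int


def loocv_perplexity(
    corpus: Sequence[Transcript],
    k: float = 1.0,
    min_count: int = 1,
) -> list[PerplexityScores]:
    """Leave-one-participant-out 1-g and 2-g perplexity for every transcript.

    For each participant the two models are fit on all other participants'
    transcripts and evaluated on the held-out transcript.  Output order
    matches input order.
    """
    if len(corpus) < 2:
        raise ValueError("leave-one-out evaluation needs at least 2 transcripts")
    out = []
    for i, held in enumerate(corpus):
        training = [t for j, t in enumerate(corpus) if j != i]
        m1 = fit_ngram(training, order=1, k=k, min_count=min_count)
        m2 = fit_ngram(training, order=2, k=k, min_count=min_count)
        out.append(
            PerplexityScores(
                participant_id=held.participant_id,
                pp_1g=perplexity(m1, held),
                pp_2g=perplexity(m2, held),
                n_tokens_scored=len(held.tokens),
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O


def read_transcripts_jsonl(path: str | Path) -> list[Transcript]:
    """Read transcripts from JSONL: one {participant_id, tokens} object per line."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            out.append(Transcript(obj["participant_id"], obj["tokens"]))
    return out


def write_transcripts_jsonl(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tr in transcripts:
            fh.write(
                json.dumps(
                    {"participant_id": tr.participant_id, "tokens": list(tr.tokens)},
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_transcript_dir(path: str | Path, pattern: str = "*.txt") -> list[Transcript]:
    """Read one plain-text file per participant; the stem is the participant id."""
    out = []
    for f in sorted(Path(path).glob(pattern)):
        toks = tokenize(f.read_text(encoding="utf-8"))
        out.append(Transcript(f.stem, toks))
    return out


def scores_to_frame(scores: Sequence[PerplexityScores]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in scores],
            "pp_1g": [s.pp_1g for s in scores],
            "pp_2g": [s.pp_2g for s in scores],
            "n_tokens_scored": [s.n_tokens_scored for s in scores],
        }
    )
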