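"""Scoring of negated predicate-argument structures (PAS).

Pre-extracted PAS records — a relation verb with its agent and theme
roles, an optional negation token and the source sentence — are filtered
to those asserting a *negated interaction* (negation present and the verb
in an interaction lexicon) and ranked by a confidence score built from
five sentence-level features:

1. argument length — long arguments hide nested structures the role
   labeller missed, so confidence decays exponentially in the longer of
   the two argument token counts;
2. sentence length — long sentences are more often misparsed, again an
   exponential decay;
3. relation type — a per-verb weight in [0, 1] from the lexicon
   (binding/co-immunoprecipitation verbs extract more reliably);
4. negation token — full weight for a common negation word, a reduced
   constant for anything unusual;
5. agent == theme — a strict multiplicative penalty; the record is still
   kept, since the sentence may carry another genuine non-interaction.

The feature subscores are each in [0, 1]; a best-case record (shortest
arguments and sentence, top-weight verb, common negation, distinct
entities) scores exactly 1.0.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import yaml

from .errors import NotACandidateError

__all__ = [
    "PASRecord",
    "ScoreConfig",
    "ScoredCandidate",
    "is_negated_interaction",
    "confidence_score",
    "rank_candidates",
    "read_pas_records",
    "write_ranked",
]

logger = logging.getLogger(__name__)

#: Verbs that specifically assert physical interaction or binding, with a
#: relation-quality weight each.  Seeded from the classic interaction
#: vocabulary; extensible via config.
DEFAULT_VERB_LEXICON: dict[str, float] = {
    "interact": 1.0,
    "bind": 1.0,
    "co-immunoprecipitate": 1.0,
    "associate": 0.8,
    "complex": 0.7,
    "co-localize": 0.6,
}

DEFAULT_COMMON_NEGATIONS = frozenset(
    {"not", "no", "never", "n't", "none", "neither", "nor", "cannot",
     "without", "fail", "fails", "failed"}
)


@dataclass(frozen=True)
class PASRecord:
    """One predicate-argument structure extracted from a sentence."""

    agent: str
    theme: str
    relation: str
    sentence: str
    negation_token: Optional[str] = None
    agent_len: int = 1
    theme_len: int = 1
    sentence_len: int = 1

    def __post_init__(self) -> None:
        if not self.relation:
            raise ValueError("relation verb must be non-empty")
        for name in ("agent_len", "theme_len", "sentence_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class ScoreConfig:
    """Weights and decay constants for the five-feature confidence score.

    ``tau_arg`` and ``tau_sent`` are e-folding lengths in tokens for the
    argument- and sentence-length decays.  ``uncommon_negation_factor``
    and ``same_entity_factor`` are the reduced multipliers for features 4
    and 5.  Feature weights are non-negative and normalized internally.
    """

    verb_lexicon: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VERB_LEXICON)
    )
    common_negations: frozenset[str] = DEFAULT_COMMON_NEGATIONS
    w_arg: float = 1.0
    w_sent: float = 1.0
    w_relation: float = 1.0
    w_negation: float = 1.0
    tau_arg: float = 10.0   # tokens
    tau_sent: float = 30.0  # tokens
    uncommon_negation_factor: float = 0.5
    same_entity_factor: float = 0.5

    def __post_init__(self) -> None:
        if not self.verb_lexicon:
            raise ValueError("verb lexicon must have at least one entry")
        if any(w < 0 or w > 1 for w in self.verb_lexicon.values()):
            raise ValueError("lexicon weights must lie in [0, 1]")
        if any(w < 0 for w in (self.w_arg, self.w_sent, self.w_relation,
                               self.w_negation)):
            raise ValueError("feature weights must be non-negative")
        if self.tau_arg <= 0 or self.tau_sent <= 0:
            raise ValueError("decay constants must be positive")
        if not (0 < self.same_entity_factor < 1):
            raise ValueError("same_entity_factor must lie strictly in (0, 1)")
        if not (0 <= self.uncommon_negation_factor <= 1):
            raise ValueError("uncommon_negation_factor must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "ScoreConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if "common_negations" in data:
            data["common_negations"] = frozenset(data["common_negations"])
        return cls(**data)


@dataclass(frozen=True)
class ScoredCandidate:
    """A PAS record that passed the negated-interaction filter, scored."""

    record: PASRecord
    score: float
    kept: bool
    same_entity: bool


def is_negated_interaction(rec: PASRecord, cfg: ScoreConfig = ScoreConfig()) -> bool:
    """True iff a negation token is present and the verb is in the lexicon."""
    return rec.negation_token is not None and rec.relation in cfg.verb_lexicon


def confidence_score(rec: PASRecord, cfg: ScoreConfig = ScoreConfig()) -> float:
    """Five-feature confidence for a negated interaction assertion, in [0, 1].

    Raises :class:`NotACandidateError` unless the record passes
    :func:`is_negated_interaction`.
    """
    if not is_negated_interaction(rec, cfg):
        raise NotACandidateError(
            f"record with relation {rec.relation!r} is not a negated "
            "interaction candidate"
        )
    s_arg = math.exp(-(max(rec.agent_len, rec.theme_len) - 1) / cfg.tau_arg)
    s_sent = math.exp(-(rec.sentence_len - 1) / cfg.tau_sent)
    s_rel = cfg.verb_lexicon[rec.relation]
    s_neg = (
        1.0
        if rec.negation_token in cfg.common_negations
        else cfg.uncommon_negation_factor
    )
    w_total = cfg.w_arg + cfg.w_sent + cfg.w_relation + cfg.w_negation
    base = (
        cfg.w_arg * s_arg
        + cfg.w_sent * s_sent
        + cfg.w_relation * s_rel
        + cfg.w_negation * s_neg
    ) / w_total
    if rec.agent == rec.theme:
        base *= cfg.same_entity_factor
    return base


def rank_candidates(
    records: Iterable[PASRecord], cfg: ScoreConfig = ScoreConfig()
) -> list[ScoredCandidate]:
    """Filter to negated-interaction candidates, score and sort.

    Descending by score; equal scores keep input order (stable sort).
    Non-candidates are excluded with a logged count.
    """
    candidates: list[ScoredCandidate] = []
    n_rejected = 0
    for rec in records:
        if not is_negated_interaction(rec, cfg):
            n_rejected += 1
            continue
        candidates.append(
            ScoredCandidate(
                record=rec,
                score=confidence_score(rec, cfg),
                kept=True,
                same_entity=rec.agent == rec.theme,
            )
        )
    if n_rejected:
        logger.info("rank_candidates: excluded %d non-candidate records",
                    n_rejected)
    candidates.sort(key=lambda c: -c.score)  # stable: ties keep input order
    return candidates


_PAS_FIELDS = ("agent", "theme", "relation", "sentence", "negation_token",
               "agent_len", "theme_len", "sentence_len")


def read_pas_records(path: str | os.PathLike) -> list[PASRecord]:
    """Read PAS records from a JSON-lines file with named fields.

    Token counts default to whitespace token counts of the corresponding
    text fields when absent.
    """
    records: list[PASRecord] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            data = json.loads(line)
            data.setdefault("agent_len", max(1, len(data["agent"].split())))
            data.setdefault("theme_len", max(1, len(data["theme"].split())))
            data.setdefault(
                "sentence_len", max(1, len(data["sentence"].split()))
            )
            records.append(
                PASRecord(**{k: data[k] for k in _PAS_FIELDS if k in data})
            )
    return records


def write_ranked(
    candidates: Sequence[ScoredCandidate], path: str | os.PathLike
) -> None:
    """Write ranked candidates as TSV: score, roles, verb, negation, sentence."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("score\tagent\ttheme\trelation\tnegation\t"
                     "same_entity\tsentence\n")
        for cand in candidates:
            rec = cand.record
            handle.write(
                f"{cand.score:.6f}\t{rec.agent}\t{rec.theme}\t{rec.relation}\t"
                f"{rec.negation_token or ''}\t"
                f"{int(cand.same_entity)}\t{rec.sentence}\n"
            )
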