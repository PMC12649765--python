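"""Pre-generation safety routing: escalate red-flag symptom reports,
decline non-medical queries, and pass everything else to the answering
pipeline.

Both detectors are deliberately lexicon/pattern-based: a safety gate must
be deterministic and its trigger inventory reviewable as plain config.

Escalation matches any red-flag phrase in the query with per-token fuzzy
tolerance (so "cant breathe" still matches "can't breathe").  A query is
out-of-scope only when two independent signals agree: its best dense
retrieval similarity against the knowledge base falls below a floor AND it
contains no medical-domain vocabulary.  The conjunction biases toward
answering: declining a genuinely medical question is treated as a worse
failure than retrieving weak evidence for it (the grounding gate still
protects the answer).  Escalation takes precedence over declining.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .index_retrieval import VectorIndex
from .textcore import token_similarity, tokenize

# red-flag symptom lexicon: trigger name -> phrases (matched fuzzily per token)
RED_FLAG_LEXICON: dict[str, tuple[str, ...]] = {
    "breathing_difficulty": (
        "can't breathe", "cant breathe", "cannot breathe", "trouble breathing",
        "difficulty breathing", "short of breath", "shortness of breath",
        "dyspnea", "gasping for air",
    ),
    "uncontrolled_bleeding": (
        "bleeding won't stop", "bleeding will not stop", "blood soaking",
        "soaking through", "uncontrolled bleeding", "bleeding heavily",
        "blood is pouring",
    ),
    "chest_pain": ("chest pain", "pressure in my chest", "chest tightness"),
    "high_fever": (
        "high fever", "fever of 102", "fever of 103", "fever of 104",
        "fever above", "temperature is 103", "temperature above",
    ),
    "loss_of_consciousness": (
        "passed out", "fainted", "lost consciousness", "unresponsive",
    ),
    "spreading_infection": (
        "red streaks", "spreading redness", "pus", "foul-smelling drainage",
    ),
    "calf_symptoms": (
        "calf swelling", "calf pain", "swollen calf", "calf is swollen",
    ),
}

# clinical vocabulary: presence of any of these tokens marks a query as
# medical-domain, vetoing the out-of-scope decline
MEDICAL_LEXICON = frozenset(
    """surgery surgical surgeon operation postoperative post-op incision wound
    stitches sutures staples drain drains dressing bandage scar scars swelling
    bruising pain painkiller painkillers medication medications nausea vomiting
    anesthesia hospital clinic doctor nurse recovery recovering healing heal
    garment compression discharge symptom symptoms prescription antibiotic
    antibiotics procedure operated""".split()
)


@dataclass
class SafetyConfig:
    scope_floor: float = 0.15
    match_threshold: float = 0.85
    red_flag_lexicon: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(RED_FLAG_LEXICON)
    )
    medical_lexicon: frozenset[str] = MEDICAL_LEXICON
    escalation_template_id: str = "escalation_handoff"
    decline_template_id: str = "out_of_scope_decline"


@dataclass(frozen=True)
class SafetyDecision:
    query_id: str
    route: str  # answer | decline_out_of_scope | escalate
    triggers: tuple[str, ...] = ()
    scope_score: float | None = None
    template_id: str | None = None


def _phrase_matches(query_tokens: tuple[str, ...], phrase: str, threshold: float) -> bool:
    p_toks = tuple(tokenize(phrase))
    n = len(p_toks)
    if n == 0 or n > len(query_tokens):
        return False
    for i in range(len(query_tokens) - n + 1):
        if all(
            token_similarity(query_tokens[i + j], p_toks[j]) >= threshold
            for j in range(n)
        ):
            return True
    return False


def detect_escalation(
    query: str, config: SafetyConfig | None = None
) -> tuple[bool, tuple[str, ...]]:
    """True iff any red-flag phrase matches the query; returns trigger names."""
    config = config or SafetyConfig()
    q_toks = tuple(tokenize(query))
    triggers = tuple(
        name
        for name, phrases in config.red_flag_lexicon.items()
        if any(_phrase_matches(q_toks, p, config.match_threshold) for p in phrases)
    )
    return bool(triggers), triggers


def detect_out_of_scope(
    query: str, index: VectorIndex, config: SafetyConfig | None = None
) -> tuple[bool, float]:
    """True iff retrieval affinity is below the floor AND no medical token.

    Returns the best raw dense cosine similarity as evidence either way.
    """
    config = config or SafetyConfig()
    score = index.best_dense_score(query)
    has_medical = any(t in config.medical_lexicon for t in tokenize(query))
    return (score < config.scope_floor and not has_medical), score


def calibrate_scope_floor(in_scope_scores: list[float], percentile: float = 5.0) -> float:
    """Data-driven floor: the given percentile of in-scope best scores."""
    if not in_scope_scores:
        raise ValueError("need at least one in-scope score")
    import numpy as np

    return float(np.percentile(np.asarray(in_scope_scores), percentile))


def route(
    query: str,
    index: VectorIndex,
    config: SafetyConfig | None = None,
    query_id: str = "",
) -> SafetyDecision:
    """Deterministic routing with precedence escalate > decline > answer."""
    config = config or SafetyConfig()
    escalate, triggers = detect_escalation(query, config)
    if escalate:
        return SafetyDecision(
            query_id=query_id,
            route="escalate",
            triggers=triggers,
            template_id=config.escalation_template_id,
        )
    oos, score = detect_out_of_scope(query, index, config)
    if oos:
        return SafetyDecision(
            query_id=query_id,
            route="decline_out_of_scope",
            scope_score=score,
            template_id=config.decline_template_id,
        )
    return SafetyDecision(query_id=query_id, route="answer", scope_score=score)
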