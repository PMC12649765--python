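"""Answer generation path: augmented prompt, draft generation, and the two
release gates (sentence-level grounding verification and heuristic numeral
validation), orchestrated behind a total ``answer_query`` that always
returns a response object.

The generator is a pluggable contract (synchronous text-in/text-out).  The
default is extractive: it selects evidence sentences by fuzzy-Jaccard
affinity to the question, which keeps the whole serving stack deterministic
and download-free.  A hosted LLM adapter can be slotted in unchanged — the
gates downstream do not care how the draft was produced.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Protocol

from .index_retrieval import EvidenceSet, VectorIndex, retrieve
from .safety_router import SafetyConfig, SafetyDecision
from .safety_router import route as safety_route
from .textcore import fuzzy_jaccard, split_sentences, tokenize

ROLE_INSTRUCTION = "You are a postoperative-care assistant"

TEMPLATES = {
    "escalation_handoff": (
        "Your message describes symptoms that need urgent medical attention. "
        "Please call your surgical team now or seek emergency care immediately. "
        "Do not wait for an online answer."
    ),
    "out_of_scope_decline": (
        "I can only help with questions about your recovery after surgery. "
        "For anything else, please ask the appropriate service. If you have a "
        "medical concern, contact your care team."
    ),
    "fallback_handoff": (
        "I could not find verified guidance for that question in your care "
        "materials. Please contact your surgical team so they can advise you "
        "directly."
    ),
}


@dataclass(frozen=True)
class AugmentedPrompt:
    role_instruction: str
    question: str
    evidence: tuple[tuple[str, str], ...]  # (chunk_id, passage) in fused order
    rendered: str
    truncated: bool = False


@dataclass
class VerifiedAnswer:
    query_id: str
    text: str
    status: str  # delivered | rejected_grounding | rejected_heuristic |
    #              declined_scope | escalated | fallback_handoff
    sentence_scores: list[float] = field(default_factory=list)
    numeric_flags: list[str] = field(default_factory=list)
    evidence_ids: list[str] = field(default_factory=list)
    triggers: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "query_id": self.query_id,
                "status": self.status,
                "text": self.text,
                "sentence_scores": [round(s, 6) for s in self.sentence_scores],
                "numeric_flags": self.numeric_flags,
                "evidence_ids": self.evidence_ids,
                "triggers": self.triggers,
            },
            sort_keys=True,
        )


@dataclass
class PipelineConfig:
    k_ann: int = 10
    k_final: int = 3
    alpha: float = 0.5
    grounding_threshold: float = 0.35
    match_threshold: float = 0.85
    generator_floor: float = 0.05
    max_sentences: int = 5
    context_budget: int = 6000
    flag_number_words: bool = False
    safety: SafetyConfig = field(default_factory=SafetyConfig)
    templates: dict[str, str] = field(default_factory=lambda: dict(TEMPLATES))


def build_prompt(
    question: str,
    evidence: EvidenceSet,
    index: VectorIndex,
    config: PipelineConfig | None = None,
) -> AugmentedPrompt:
    """Render role instruction + question + tagged evidence passages.

    Purely functional in its inputs; if the render exceeds the context
    budget, evidence is truncated from rank 3 downward and flagged.
    """
    config = config or PipelineConfig()
    if not evidence.candidates:
        raise ValueError("evidence set is empty")
    passages = [(c.chunk_id, index.chunks[c.chunk_id].text) for c in evidence.candidates]

    def render(p: list[tuple[str, str]]) -> str:
        parts = [ROLE_INSTRUCTION, "", f"Question: {question}", "", "Evidence:"]
        parts += [f"[{cid}] {text}" for cid, text in p]
        return "\n".join(parts)

    truncated = False
    while len(render(passages)) > config.context_budget and len(passages) > 1:
        passages = passages[:-1]
        truncated = True
    return AugmentedPrompt(
        role_instruction=ROLE_INSTRUCTION,
        question=question,
        evidence=tuple(passages),
        rendered=render(passages),
        truncated=truncated,
    )


class Generator(Protocol):
    def generate(self, prompt: AugmentedPrompt) -> str: ...


class ExtractiveGenerator:
    """Deterministic extractive draft generator.

    Scores each evidence sentence by fuzzy Jaccard against the question,
    keeps those at or above ``floor`` in evidence-rank-then-position order,
    up to ``max_sentences``, and joins them into prose.  Output sentences
    are by construction a subset of the evidence sentences.
    """

    def __init__(self, floor: float = 0.05, max_sentences: int = 5, match_threshold: float = 0.85):
        self.floor = floor
        self.max_sentences = max_sentences
        self.match_threshold = match_threshold

    def generate(self, prompt: AugmentedPrompt) -> str:
        q_tokens = tokenize(prompt.question)
        scored: list[tuple[float, int, int, str]] = []
        seen: set[str] = set()
        for rank, (_, passage) in enumerate(prompt.evidence):
            for pos, sent in enumerate(split_sentences(passage)):
                if sent in seen:
                    continue
                seen.add(sent)
                score = fuzzy_jaccard(tokenize(sent), q_tokens, self.match_threshold)
                if score >= self.floor:
                    scored.append((score, rank, pos, sent))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        picked = sorted(scored[: self.max_sentences], key=lambda t: (t[1], t[2]))
        return " ".join(sent for _, _, _, sent in picked)


def generate_draft(prompt: AugmentedPrompt, generator: Generator) -> str:
    return generator.generate(prompt)


def _evidence_units(evidence_texts: list[str]) -> list[frozenset[str]]:
    """Grounding comparison units: each chunk's full token set plus each of
    its sentences' token sets (sentence-level alignment for short claims)."""
    units: list[frozenset[str]] = []
    for text in evidence_texts:
        units.append(tokenize(text).unique)
        for sent in split_sentences(text):
            units.append(tokenize(sent).unique)
    return units


def grounding_verify(
    draft: str,
    evidence_texts: list[str],
    threshold: float = 0.35,
    match_threshold: float = 0.85,
) -> tuple[list[float], bool, list[str]]:
    """Score every draft sentence against the evidence; accept iff all pass.

    A sentence's grounding confidence is its best fuzzy Jaccard against any
    evidence unit.  Returns (scores, accepted, failing sentences).
    """
    if not draft.strip():
        raise ValueError("draft is empty")
    units = _evidence_units(evidence_texts)
    scores: list[float] = []
    failing: list[str] = []
    for sent in split_sentences(draft):
        toks = tokenize(sent)
        score = max((fuzzy_jaccard(toks, u, match_threshold) for u in units), default=0.0)
        scores.append(score)
        if score < threshold:
            failing.append(sent)
    return scores, not failing, failing


_NUMERAL_RE = re.compile(r"\d[\d,]*(?:\.\d+)?")
_CITATION_RE = re.compile(r"\[\d+\]|\bet al\.")

_NUMBER_WORDS = {
    "one": "1", "two": "2", "three": "3", "four": "4", "five": "5",
    "six": "6", "seven": "7", "eight": "8", "nine": "9", "ten": "10",
}


def _normalize_numeral(raw: str) -> str:
    s = raw.replace(",", "")
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s


def extract_numerals(text: str, number_words: bool = False) -> set[str]:
    found = {_normalize_numeral(m.group(0)) for m in _NUMERAL_RE.finditer(text)}
    if number_words:
        for t in tokenize(text):
            if t in _NUMBER_WORDS:
                found.add(_NUMBER_WORDS[t])
    return found


def heuristic_validate(
    draft: str, evidence_texts: list[str], number_words: bool = False
) -> tuple[list[str], bool]:
    """Screen for fabricated numerals and unsupported citation patterns.

    Every numeral in the draft must occur (after literal normalization:
    commas stripped, trailing decimal zeros dropped) as a numeral somewhere
    in the evidence.  No unit conversion is attempted — "2 weeks" does not
    license "14 days"; such mismatches are flagged for review.
    """
    if not draft.strip():
        raise ValueError("draft is empty")
    evidence_all = " ".join(evidence_texts)
    supported = extract_numerals(evidence_all, number_words)
    flags = sorted(extract_numerals(draft, number_words) - supported)
    for m in _CITATION_RE.finditer(draft):
        if m.group(0) not in evidence_all:
            flags.append(m.group(0))
    return flags, not flags


class AnswerPipeline:
    """End-to-end serving: safety route, retrieve, generate, gate, deliver.

    Total by contract: every query yields a ``VerifiedAnswer`` — safety
    templates for escalation/decline, the draft when both gates pass, and a
    safe handoff template on any gate failure or internal error.  Evidence
    chunk ids are always recorded for auditing.
    """

    def __init__(
        self,
        index: VectorIndex,
        config: PipelineConfig | None = None,
        generator: Generator | None = None,
    ) -> None:
        self.index = index
        self.config = config or PipelineConfig()
        self.generator = generator or ExtractiveGenerator(
            floor=self.config.generator_floor,
            max_sentences=self.config.max_sentences,
            match_threshold=self.config.match_threshold,
        )

    def _template(self, key: str) -> str:
        return self.config.templates[key]

    def route(self, query: str, query_id: str = "") -> SafetyDecision:
        return safety_route(query, self.index, self.config.safety, query_id)

    def answer_query(self, query: str, query_id: str = "") -> VerifiedAnswer:
        try:
            return self._answer(query, query_id)
        except Exception:  # gate failures never surface; totality contract
            return VerifiedAnswer(
                query_id=query_id,
                text=self._template("fallback_handoff"),
                status="fallback_handoff",
            )

    def _answer(self, query: str, query_id: str) -> VerifiedAnswer:
        decision = self.route(query, query_id)
        if decision.route == "escalate":
            return VerifiedAnswer(
                query_id=query_id,
                text=self._template("escalation_handoff"),
                status="escalated",
                triggers=list(decision.triggers),
            )
        if decision.route == "decline_out_of_scope":
            return VerifiedAnswer(
                query_id=query_id,
                text=self._template("out_of_scope_decline"),
                status="declined_scope",
            )
        cfg = self.config
        evidence = retrieve(
            query, self.index, query_id=query_id,
            k_ann=cfg.k_ann, k_final=cfg.k_final, alpha=cfg.alpha,
        )
        if not evidence.candidates:
            return VerifiedAnswer(
                query_id=query_id,
                text=self._template("fallback_handoff"),
                status="fallback_handoff",
            )
        prompt = build_prompt(query, evidence, self.index, cfg)
        draft = generate_draft(prompt, self.generator)
        evidence_ids = evidence.chunk_ids
        if not draft.strip():
            return VerifiedAnswer(
                query_id=query_id,
                text=self._template("fallback_handoff"),
                status="fallback_handoff",
                evidence_ids=evidence_ids,
            )
        evidence_texts = [self.index.chunks[cid].text for cid in evidence_ids]
        scores, grounded, _ = grounding_verify(
            draft, evidence_texts, cfg.grounding_threshold, cfg.match_threshold
        )
        if not grounded:
            return VerifiedAnswer(
                query_id=query_id,
                text=self._template("fallback_handoff"),
                status="rejected_grounding",
                sentence_scores=scores,
                evidence_ids=evidence_ids,
            )
        flags, clean = heuristic_validate(draft, evidence_texts, cfg.flag_number_words)
        if not clean:
            return VerifiedAnswer(
                query_id=query_id,
                text=self._template("fallback_handoff"),
                status="rejected_heuristic",
                sentence_scores=scores,
                numeric_flags=flags,
                evidence_ids=evidence_ids,
            )
        return VerifiedAnswer(
            query_id=query_id,
            text=draft,
            status="delivered",
            sentence_scores=scores,
            evidence_ids=evidence_ids,
        )
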