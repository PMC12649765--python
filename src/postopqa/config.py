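"""Run configuration: one serializable object holding every numeric
constant of the stack (chunking, index, retrieval, gating, safety,
evaluation), so a saved config reproduces a run bit-for-bit through the
deterministic stages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .answer_pipeline import PipelineConfig
from .index_retrieval import IndexConfig


@dataclass
class EvalConfig:
    tau_support: float = 0.35
    mmr_lambda: float = 0.7
    eval_k: int = 4
    eval_chunk_words: int = 300


@dataclass
class RunConfig:
    seed: int = 0
    chunk_limit: int = 500
    paragraph_breaks: bool = True
    index: IndexConfig = field(default_factory=IndexConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        # frozensets and tuples are not JSON/YAML friendly
        safety = d["pipeline"]["safety"]
        safety["medical_lexicon"] = sorted(safety["medical_lexicon"])
        safety["red_flag_lexicon"] = {
            k: list(v) for k, v in safety["red_flag_lexicon"].items()
        }
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        from .safety_router import SafetyConfig

        idx = IndexConfig(**raw.get("index", {}))
        pipe_raw = dict(raw.get("pipeline", {}))
        safety_raw = dict(pipe_raw.pop("safety", {}))
        if "medical_lexicon" in safety_raw:
            safety_raw["medical_lexicon"] = frozenset(safety_raw["medical_lexicon"])
        if "red_flag_lexicon" in safety_raw:
            safety_raw["red_flag_lexicon"] = {
                k: tuple(v) for k, v in safety_raw["red_flag_lexicon"].items()
            }
        pipe = PipelineConfig(**pipe_raw, safety=SafetyConfig(**safety_raw))
        return cls(
            seed=raw.get("seed", 0),
            chunk_limit=raw.get("chunk_limit", 500),
            paragraph_breaks=raw.get("paragraph_breaks", True),
            index=idx,
            pipeline=pipe,
            evaluation=EvalConfig(**raw.get("evaluation", {})),
        )
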