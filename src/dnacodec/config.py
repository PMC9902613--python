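"""Schema-validated configuration files (JSON or YAML) for the CLI.

The document is a nested object with blocks ``codebook``, ``inner``,
``decoder``, ``fountain`` and a global ``seed``; unknown keys anywhere are
rejected so typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .codebook import (
    Codebook,
    ConcatenationScheme,
    ConstraintSpec,
    generate_codebook,
    load_codebook,
    load_concatenation_scheme,
)
from .fountain import FountainConfig
from .pipeline import CodecParams
from .stack import ChannelPriors


class ConfigError(ValueError):
    pass


_CODEBOOK_KEYS = {"fasta", "scheme", "length", "constraints"}
_CONSTRAINT_KEYS = {"gc_min", "gc_max", "gc_interval", "hp_max", "motifs",
                    "revcomp_motifs"}
_INNER_KEYS = {"step_size"}
_DECODER_KEYS = {"stack_size", "pop_count", "penalty", "max_iterations",
                 "budget_schedule", "revcomp_retry",
                 "p_sub", "p_ins", "p_del", "p_t", "rate"}
_FOUNTAIN_KEYS = {"chunk_size", "overhead", "use_header", "use_packet_crc",
                  "packet_crc_bytes", "soliton_c", "soliton_delta",
                  "fallback_budget"}
_TOP_KEYS = {"codebook", "inner", "decoder", "fountain", "seed", "filename"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass
class CodecConfig:
    """Parsed configuration; `resolve` turns it into runtime objects."""

    codebook: dict = field(default_factory=dict)
    inner: dict = field(default_factory=dict)
    decoder: dict = field(default_factory=dict)
    fountain: dict = field(default_factory=dict)
    seed: int = 0
    filename: str | None = None

    @classmethod
    def from_dict(cls, doc: dict) -> "CodecConfig":
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
        _check_keys(doc, _TOP_KEYS, "config")
        cb = doc.get("codebook", {})
        _check_keys(cb, _CODEBOOK_KEYS, "codebook")
        _check_keys(cb.get("constraints", {}), _CONSTRAINT_KEYS,
                    "codebook.constraints")
        inner = doc.get("inner", {})
        _check_keys(inner, _INNER_KEYS, "inner")
        decoder = doc.get("decoder", {})
        _check_keys(decoder, _DECODER_KEYS, "decoder")
        ft = doc.get("fountain", {})
        _check_keys(ft, _FOUNTAIN_KEYS, "fountain")
        return cls(cb, inner, decoder, ft, int(doc.get("seed", 0)),
                   doc.get("filename"))

    @classmethod
    def from_file(cls, path) -> "CodecConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            doc = yaml.safe_load(text) or {}
        else:
            doc = json.loads(text)
        return cls.from_dict(doc)

    # -- resolution --------------------------------------------------------

    def constraint_spec(self) -> ConstraintSpec:
        c = self.codebook.get("constraints", {})
        return ConstraintSpec(
            gc_min=c.get("gc_min", 0.0),
            gc_max=c.get("gc_max", 1.0),
            gc_interval=c.get("gc_interval", 1),
            hp_max=c.get("hp_max"),
            forbidden_motifs=tuple(c.get("motifs", ())),
            revcomp_motifs=c.get("revcomp_motifs", False),
        )

    def resolve_codebook(self) -> tuple[Codebook, ConcatenationScheme]:
        if "fasta" in self.codebook:
            cb = load_codebook(self.codebook["fasta"])
            if "scheme" in self.codebook and self.codebook["scheme"]:
                scheme = load_concatenation_scheme(self.codebook["scheme"])
            else:
                scheme = ConcatenationScheme()
            return cb, scheme
        if "length" in self.codebook:
            return generate_codebook(self.constraint_spec(),
                                     int(self.codebook["length"]))
        raise ConfigError(
            "codebook block needs either a 'fasta' path or constraints + 'length'"
        )

    def params(self, filename: str = "file") -> CodecParams:
        ft = FountainConfig(
            chunk_size=self.fountain.get("chunk_size", 16),
            overhead=self.fountain.get("overhead", 0.5),
            use_header=self.fountain.get("use_header", True),
            use_packet_crc=self.fountain.get("use_packet_crc", False),
            packet_crc_bytes=self.fountain.get("packet_crc_bytes", 2),
            soliton_c=self.fountain.get("soliton_c", 0.1),
            soliton_delta=self.fountain.get("soliton_delta", 0.05),
            fallback_budget=self.fountain.get("fallback_budget", 50),
        )
        priors = ChannelPriors(
            p_sub=self.decoder.get("p_sub", 0.01),
            p_ins=self.decoder.get("p_ins", 0.0),
            p_del=self.decoder.get("p_del", 0.0),
            p_t=self.decoder.get("p_t"),
            R=self.decoder.get("rate"),
        )
        return CodecParams(
            fountain=ft,
            step_size=self.inner.get("step_size", 4),
            stack_size=self.decoder.get("stack_size", 2000),
            pop_count=self.decoder.get("pop_count", 1),
            penalty=self.decoder.get("penalty", 0.0),
            max_iterations=self.decoder.get("max_iterations", 200_000),
            budget_schedule=tuple(self.decoder.get("budget_schedule", (30_000,))),
            revcomp_retry=self.decoder.get("revcomp_retry", False),
            priors=priors,
            filename=self.filename or filename,
            first_seed=1,
        )
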