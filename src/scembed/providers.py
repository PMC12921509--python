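"""Embedding providers: turning feature/label names into vectors.

A provider pairs a ``describe`` step (name -> text, via a prompt template)
with an ``embed`` step (text -> fixed-length vector). Real language-model
backends can be plugged in behind the same :class:`Provider` protocol; the
shipped :class:`HashEmbeddingProvider` is a fully offline, deterministic
provider that maps any string to a seeded pseudo-random unit vector, so the
entire pipeline runs and tests without network access.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .data import FeatureEmbeddingTable, LabelEmbeddingTable, ValidationError

DEFAULT_TEMPLATES = {
    "gene": "Summarize the biological function of the gene {}.",
    "protein": "Summarize the biological function of the protein {}.",
    "cell_type": "Summarize the characteristics and function of the cell type {}.",
}


@dataclass(frozen=True)
class PromptTemplate:
    """Template with exactly one ``{}`` placeholder for the feature name."""

    template: str
    target_kind: str = "gene"

    def __post_init__(self):
        if self.template.count("{}") != 1:
            raise ValidationError(
                "template must contain exactly one '{}' placeholder"
            )
        if self.target_kind not in DEFAULT_TEMPLATES:
            raise ValidationError(f"unknown target kind {self.target_kind!r}")

    @classmethod
    def default(cls, target_kind: str = "gene") -> "PromptTemplate":
        return cls(DEFAULT_TEMPLATES[target_kind], target_kind)


def render_prompt(tpl: PromptTemplate, name: str) -> str:
    """Substitute ``name`` into the template, verbatim."""
    if not name:
        raise ValidationError("feature name must be nonempty")
    return tpl.template.replace("{}", name)


@runtime_checkable
class Provider(Protocol):
    """Contract: deterministic ``describe`` and ``embed`` of fixed dim."""

    dim: int

    def describe(self, name: str) -> str: ...

    def embed(self, text: str) -> np.ndarray: ...


def hash_embed(name_or_text: str, t: int, seed: int = 0) -> np.ndarray:
    """Deterministic unit vector of length ``t`` keyed by a string.

    The string is hashed (SHA-256, together with ``seed``) into the state of
    a PRNG that draws ``t`` standard normals, which are then L2-normalized.
    Distinct strings therefore give near-orthogonal vectors for large ``t``,
    and identical inputs always give identical output, across platforms.
    """
    if t <= 0:
        raise ValidationError("embedding dimension t must be >= 1")
    digest = hashlib.sha256(f"{seed}\x00{name_or_text}".encode()).digest()
    rng = np.random.default_rng(np.frombuffer(digest, dtype=np.uint64))
    v = rng.standard_normal(t)
    return v / np.linalg.norm(v)


@dataclass
class HashEmbeddingProvider:
    """Offline deterministic provider built on :func:`hash_embed`."""

    dim: int = 64
    seed: int = 0
    template: PromptTemplate = field(default_factory=PromptTemplate.default)

    def describe(self, name: str) -> str:
        return render_prompt(self.template, name)

    def embed(self, text: str) -> np.ndarray:
        return hash_embed(text, self.dim, self.seed)


def build_table(
    names: list[str],
    provider: Provider,
    tpl: PromptTemplate | None = None,
    label_table: bool = False,
) -> FeatureEmbeddingTable:
    """Describe then embed every name, preserving order; names must be unique.

    Descriptions/embeddings are cached per distinct name so repeated calls
    (and repeated names across calls) embed each name exactly once.
    """
    if len(set(names)) != len(names):
        raise ValidationError("names must be unique")
    tpl = tpl or getattr(provider, "template", None) or PromptTemplate.default()
    cache: dict[str, np.ndarray] = {}
    failed: list[str] = []
    rows = []
    for name in names:
        if name not in cache:
            try:
                text = render_prompt(tpl, name)
                cache[name] = np.asarray(provider.embed(text), dtype=float)
            except Exception:
                failed.append(name)
                continue
        rows.append(cache[name])
    if failed:
        raise ValidationError(f"provider failed for names: {failed[:20]}")
    dim = provider.dim
    vectors = np.array(rows, dtype=float) if rows else np.zeros((0, dim))
    cls = LabelEmbeddingTable if label_table else FeatureEmbeddingTable
    return cls(list(names), vectors)
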