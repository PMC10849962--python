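"""One-hot encoding of categorical reaction conditions.

Two dataset regimes are supported through the same API: the experimental
(plate) regime encodes ligand and solvent only — the catalyst, boron
source and numeric parameters (T = 80 °C, t = 16 h, c = 0.2 M) are fixed
by the plate — while the literature regime also encodes reagent and
catalyst.  Categories are sorted lexicographically so the vocabulary is
reproducible across platforms and input orderings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EXPERIMENTAL_FIELDS",
    "LITERATURE_FIELDS",
    "ConditionVocabulary",
    "UnseenCategoryError",
    "fit_vocabulary",
    "encode_conditions",
    "decode_conditions",
    "condition_space_size",
]

EXPERIMENTAL_FIELDS = ("ligand", "solvent")
LITERATURE_FIELDS = ("ligand", "solvent", "reagent", "catalyst")


class UnseenCategoryError(KeyError):
    """A condition value absent from the fitted vocabulary."""


@dataclass
class ConditionVocabulary:
    """Ordered category lists per condition field."""

    fields: tuple[str, ...]
    categories: dict[str, list[str]]
    dataset_hash: str = ""
    offsets: dict[str, int] = field(init=False)

    def __post_init__(self):
        off, cursor = {}, 0
        for f in self.fields:
            off[f] = cursor
            cursor += len(self.categories[f])
        self.offsets = off

    @property
    def width(self) -> int:
        return sum(len(self.categories[f]) for f in self.fields)

    def cardinalities(self) -> tuple[int, ...]:
        return tuple(len(self.categories[f]) for f in self.fields)

    def to_json(self) -> str:
        return json.dumps(
            {
                "fields": list(self.fields),
                "categories": self.categories,
                "dataset_hash": self.dataset_hash,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ConditionVocabulary":
        d = json.loads(text)
        return cls(tuple(d["fields"]), d["categories"], d["dataset_hash"])


def fit_vocabulary(records, fields=EXPERIMENTAL_FIELDS) -> ConditionVocabulary:
    """Collect the distinct values of each condition field, sorted.

    Deterministic and insensitive to record order.
    """
    if not records:
        raise ValueError("cannot fit a condition vocabulary on zero records")
    cats = {f: sorted({getattr(r, f) for r in records}) for f in fields}
    digest = hashlib.sha256(
        "\n".join(sorted(r.rxn_id for r in records)).encode()
    ).hexdigest()[:16]
    return ConditionVocabulary(tuple(fields), cats, digest)


def encode_conditions(record, vocab: ConditionVocabulary) -> np.ndarray:
    """Concatenated one-hot blocks for a record's condition values.

    Unseen categories raise :class:`UnseenCategoryError` naming the field
    and value — there is no silent "other" bucket.
    """
    vec = np.zeros(vocab.width, dtype=float)
    for f in vocab.fields:
        value = getattr(record, f)
        cats = vocab.categories[f]
        try:
            pos = cats.index(value)
        except ValueError:
            raise UnseenCategoryError(
                f"unseen category for field {f!r}: {value!r} (known: {cats})"
            ) from None
        vec[vocab.offsets[f] + pos] = 1.0
    return vec


def decode_conditions(vector: np.ndarray, vocab: ConditionVocabulary) -> dict[str, str]:
    """Inverse of :func:`encode_conditions`; validates block sums."""
    out = {}
    for f in vocab.fields:
        lo = vocab.offsets[f]
        block = vector[lo : lo + len(vocab.categories[f])]
        if block.sum() != 1.0:
            raise ValueError(f"block for field {f!r} does not sum to 1")
        out[f] = vocab.categories[f][int(np.argmax(block))]
    return out


def condition_space_size(vocab: ConditionVocabulary) -> int:
    """Number of joint condition combinations (product of cardinalities)."""
    return int(np.prod([len(vocab.categories[f]) for f in vocab.fields], dtype=object))
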