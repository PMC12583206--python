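"""Compositional treatment embeddings and their ontology regularizers.

A treatment embedding is the sum of a class-shared prototype and a
treatment-specific offset, e(a) = E_sym(α(a)) + E_spec(a), so that
pharmacologically related interventions share parameters.  Three
regularizers shape the embedding geometry:

* a margin loss keeping intra-class embeddings within squared distance δ,
* a kernel-alignment loss pulling squared distances toward 1 − K(a_i, a_j)
  for the symbolic affinity kernel K,
* an entropy-aware penalty on the class-attention distribution that, with a
  positive weight, rewards spread-out attention (the attention itself is a
  softmax over inner products between the latent state and class
  prototypes).

All functions operate on autodiff tensors so they can serve directly as
training losses; plain arrays are accepted and promoted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor, log, relu, softmax
from .cohort import TreatmentOntology

__all__ = [
    "EmbeddingTables",
    "embed_treatment",
    "symbolic_margin_loss",
    "kernel_alignment_loss",
    "class_attention",
    "attention_entropy_penalty",
    "export_embeddings_tsv",
]


@dataclass
class EmbeddingTables:
    """Class-prototype and treatment-specific embedding tables.

    `E_sym` has one row per class (ordered as `classes`), `E_spec` one row
    per treatment (ordered as `vocab`); both share the embedding dimension m.
    """

    classes: list[str]
    vocab: list[str]
    E_sym: Tensor
    E_spec: Tensor
    margin: float = 0.1

    def __post_init__(self) -> None:
        self.E_sym = as_tensor(self.E_sym)
        self.E_spec = as_tensor(self.E_spec)
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.E_sym.shape != (len(self.classes), self.E_sym.shape[1]):
            raise ValueError("E_sym row count does not match class list")
        if self.E_spec.shape[0] != len(self.vocab):
            raise ValueError("E_spec row count does not match vocabulary")
        if self.E_sym.shape[1] != self.E_spec.shape[1]:
            raise ValueError("E_sym and E_spec must share the embedding dimension")
        self._class_row = {c: i for i, c in enumerate(self.classes)}
        self._vocab_row = {a: i for i, a in enumerate(self.vocab)}

    @property
    def m(self) -> int:
        return self.E_sym.shape[1]

    @classmethod
    def from_ontology(
        cls,
        ontology: TreatmentOntology,
        m: int,
        rng: np.random.Generator,
        scale: float = 0.1,
        margin: float = 0.1,
    ) -> "EmbeddingTables":
        classes = ontology.classes
        vocab = ontology.sorted_vocabulary()
        return cls(
            classes=classes,
            vocab=vocab,
            E_sym=Tensor(scale * rng.normal(size=(len(classes), m)), requires_grad=True),
            E_spec=Tensor(scale * rng.normal(size=(len(vocab), m)), requires_grad=True),
            margin=margin,
        )


def embed_treatment(a: str, tables: EmbeddingTables, ontology: TreatmentOntology) -> Tensor:
    """e(a) = E_sym(α(a)) + E_spec(a)."""
    cls = ontology.alpha(a)
    try:
        ci = tables._class_row[cls]
        vi = tables._vocab_row[a]
    except KeyError as exc:
        raise KeyError(f"treatment {a!r} / class {cls!r} missing from embedding tables") from exc
    return tables.E_sym[ci] + tables.E_spec[vi]


def _sq_dist(u: Tensor, v: Tensor) -> Tensor:
    d = u - v
    return (d * d).sum()


def symbolic_margin_loss(tables: EmbeddingTables, ontology: TreatmentOntology) -> Tensor:
    """Hinge penalty on intra-class pairs exceeding squared distance δ.

    Unordered pairs i < j within each class; classes with fewer than two
    members contribute nothing.
    """
    total = as_tensor(0.0)
    for cls in ontology.classes:
        members = [a for a in ontology.members(cls) if a in tables._vocab_row]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ei = embed_treatment(members[i], tables, ontology)
                ej = embed_treatment(members[j], tables, ontology)
                total = total + relu(_sq_dist(ei, ej) - tables.margin)
    return total


def kernel_alignment_loss(tables: EmbeddingTables, ontology: TreatmentOntology) -> Tensor:
    """Squared discrepancy between embedding distances and 1 − K over all pairs.

    Enumerates unordered vocabulary pairs i < j; the kernel is defaulted by
    class co-membership where no explicit entry exists.
    """
    vocab = [a for a in ontology.sorted_vocabulary() if a in tables._vocab_row]
    total = as_tensor(0.0)
    for i in range(len(vocab)):
        ei = embed_treatment(vocab[i], tables, ontology)
        for j in range(i + 1, len(vocab)):
            ej = embed_treatment(vocab[j], tables, ontology)
            target = 1.0 - ontology.kernel(vocab[i], vocab[j])
            diff = _sq_dist(ei, ej) - target
            total = total + diff * diff
    return total


def class_attention(
    z,
    tables: EmbeddingTables,
    ontology: TreatmentOntology,
    projection: Tensor | None = None,
) -> Tensor:
    """Softmax attention over class prototypes, α_c ∝ exp⟨z, e_c⟩.

    `projection` (m × d_z) maps the latent state into embedding space when
    the dimensions differ; it must be supplied in that case.
    """
    if not ontology.classes:
        raise ValueError("ontology has no classes")
    z = as_tensor(z)
    if projection is not None:
        z = projection @ z
    if z.shape[-1] != tables.m:
        raise ValueError(
            f"latent dimension {z.shape[-1]} != embedding dimension {tables.m}; "
            "supply a projection"
        )
    rows = [tables._class_row[c] for c in ontology.classes]
    scores = tables.E_sym[rows] @ z
    return softmax(scores, axis=-1)


def attention_entropy_penalty(attention) -> Tensor:
    """Negative Shannon entropy, Σ_c α_c ln α_c (0·ln 0 := 0).

    Adding this with a positive weight rewards high-entropy (spread-out)
    attention, discouraging over-concentration on a single class.
    """
    att = as_tensor(attention)
    pos = att.data > 0.0
    if not pos.any():
        return as_tensor(0.0)
    p = att[pos]
    return (p * log(p)).sum()


def export_embeddings_tsv(tables: EmbeddingTables, ontology: TreatmentOntology, path) -> None:
    """Write (id, class, m values) rows for external visualization."""
    with open(path, "w") as fh:
        fh.write("id\tclass\t" + "\t".join(f"e{i}" for i in range(tables.m)) + "\n")
        for a in tables.vocab:
            e = embed_treatment(a, tables, ontology).data
            fh.write(a + "\t" + ontology.alpha(a) + "\t" + "\t".join(f"{v:.8g}" for v in e) + "\n")
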