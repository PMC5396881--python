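"""MeSH vocabulary: descriptor -> tree numbers, and term categorization.

The analysis buckets candidate MeSH descriptors into three categories by
their position in the MeSH tree:

* **drug** — descriptors on a supplied FDA-approved drug list that exist
  in the vocabulary;
* **protein** — descriptors with a tree number under ``D08`` (enzymes)
  or ``D12.776`` (proteins);
* **phenomena** — descriptors under ``G03``, ``G04``, ``G06`` or ``G07``
  (metabolism, cell physiology, digestive/respiratory and physiological
  phenomena branches).

Descriptors naming an interaction type (see
:data:`meshddi.corpus.INTERACTION_TERMS`) form a fourth, reserved
category: they define the corpus partition and are never candidates.
Precedence when a descriptor sits in several branches:
interaction > drug > protein > phenomena > other.

Two on-disk formats are read: the official MeSH ASCII descriptor format
(``*NEWRECORD`` / ``MH = `` / ``MN = ``) and a simplified two-column TSV
(``descriptor<TAB>tree_numbers`` with ``;``-joined tree numbers).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from ._text import norm_term

logger = logging.getLogger(__name__)

__all__ = [
    "MeshVocabulary",
    "TermCategory",
    "VocabFormatError",
    "load_mesh_ascii",
    "load_mesh_tsv",
    "write_mesh_tsv",
    "classify_term",
    "candidate_terms",
    "PROTEIN_BRANCHES",
    "PHENOMENA_BRANCHES",
]

PROTEIN_BRANCHES = ("D08", "D12.776")
PHENOMENA_BRANCHES = ("G03", "G04", "G06", "G07")

_TREE_RE = re.compile(r"^[A-Z]\d+(\.\d+)*$")


class VocabFormatError(ValueError):
    """Malformed vocabulary input."""


class TermCategory(str, Enum):
    DRUG = "drug"
    PROTEIN = "protein"
    PHENOMENA = "phenomena"
    INTERACTION = "interaction"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CANDIDATE_CATEGORIES = (TermCategory.DRUG, TermCategory.PROTEIN, TermCategory.PHENOMENA)


def _tree_under(tree: str, branch: str) -> bool:
    """Prefix match on dot-separated segments ("D12.77" is NOT under "D12.776")."""
    t = tree.split(".")
    b = branch.split(".")
    return t[: len(b)] == b


@dataclass
class MeshVocabulary:
    """Descriptor -> tree-number map with a drug list and optional synonyms.

    Lookup is case-insensitive on NFC-normalized names; the stored keys
    keep the vocabulary's canonical casing.
    """

    descriptors: dict[str, list[str]] = field(default_factory=dict)
    drug_list: set[str] = field(default_factory=set)
    entry_terms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, trees in self.descriptors.items():
            for t in trees:
                if not _TREE_RE.match(t):
                    raise VocabFormatError(f"bad tree number {t!r} for descriptor {name!r}")
        self._index: dict[str, str] = {norm_term(k): k for k in self.descriptors}
        bad = self.drug_list - set(self.descriptors)
        if bad:
            raise VocabFormatError(f"drug_list entries missing from descriptors: {sorted(bad)[:5]}")

    def canonical(self, name: str, resolve_synonyms: bool = False) -> str | None:
        """Canonical descriptor for ``name``, or None if unknown."""
        key = norm_term(name)
        hit = self._index.get(key)
        if hit is None and resolve_synonyms:
            target = self.entry_terms.get(key)
            if target is not None:
                hit = self._index.get(norm_term(target))
        return hit

    def tree_numbers(self, name: str) -> list[str]:
        canon = self.canonical(name)
        return self.descriptors.get(canon, []) if canon else []

    def add_descriptor(self, name: str, trees: Iterable[str] = (), is_drug: bool = False) -> None:
        trees = list(trees)
        for t in trees:
            if not _TREE_RE.match(t):
                raise VocabFormatError(f"bad tree number {t!r} for descriptor {name!r}")
        self.descriptors.setdefault(name, []).extend(
            t for t in trees if t not in self.descriptors.get(name, [])
        )
        self._index[norm_term(name)] = name
        if is_drug:
            self.drug_list.add(name)

    def set_drug_list(self, names: Iterable[str]) -> tuple[int, list[str]]:
        """Mark descriptors as FDA-approved drugs by (normalized) name.

        Names absent from the vocabulary are logged and dropped.
        Returns (number matched, unmatched names).
        """
        unmatched: list[str] = []
        for raw in names:
            name = raw.strip()
            if not name:
                continue
            canon = self.canonical(name)
            if canon is None:
                unmatched.append(name)
            else:
                self.drug_list.add(canon)
        if unmatched:
            logger.info(
                "%d drug-list names not found in the vocabulary (e.g. %s)",
                len(unmatched), unmatched[:3],
            )
        return len(self.drug_list), unmatched

    def __contains__(self, name: str) -> bool:
        return self.canonical(name) is not None

    def __len__(self) -> int:
        return len(self.descriptors)


def _as_handle(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    p = Path(source)
    if "\n" not in str(source) and p.exists():
        return p.open("r", encoding="utf-8")
    if isinstance(source, str):
        return io.StringIO(source)
    raise TypeError(f"cannot read vocabulary from {type(source)!r}")


def load_mesh_ascii(source) -> MeshVocabulary:
    """Load the official MeSH ASCII descriptor format.

    Records are separated by ``*NEWRECORD``; ``MH = `` carries the heading,
    ``MN = `` lines the tree numbers, ``ENTRY``/``PRINT ENTRY`` lines the
    synonym entry terms (text before the first ``|``).  Descriptors without
    tree numbers are retained with an empty tree list.
    """
    handle = _as_handle(source)
    descriptors: dict[str, list[str]] = {}
    entry_terms: dict[str, str] = {}
    current_mh: str | None = None
    current_mn: list[str] = []
    current_entries: list[str] = []
    record_index = -1

    def flush() -> None:
        if record_index < 0:
            return
        if current_mh is None:
            if current_mn:
                raise VocabFormatError(
                    f"record {record_index}: MN lines without an MH heading"
                )
            return
        descriptors[current_mh] = list(current_mn)
        for ent in current_entries:
            entry_terms[norm_term(ent)] = current_mh

    for line in handle:
        line = line.rstrip("\n")
        if line.strip() == "*NEWRECORD":
            flush()
            record_index += 1
            current_mh, current_mn, current_entries = None, [], []
        elif line.startswith("MH = "):
            current_mh = line[5:].strip()
        elif line.startswith("MN = "):
            current_mn.append(line[5:].strip())
        elif line.startswith("ENTRY = ") or line.startswith("PRINT ENTRY = "):
            value = line.split("= ", 1)[1]
            current_entries.append(value.split("|", 1)[0].strip())
    flush()
    return MeshVocabulary(descriptors=descriptors, entry_terms=entry_terms)


def load_mesh_tsv(source) -> MeshVocabulary:
    """Load the simplified TSV dialect (header ``descriptor<TAB>tree_numbers``)."""
    handle = _as_handle(source)
    lines = [ln.rstrip("\n") for ln in handle]
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not lines:
        return MeshVocabulary()
    header = lines[0].split("\t")
    if [h.strip().lower() for h in header[:2]] != ["descriptor", "tree_numbers"]:
        raise VocabFormatError(f"unexpected TSV header: {lines[0]!r}")
    descriptors: dict[str, list[str]] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        name = parts[0].strip()
        trees_cell = parts[1].strip() if len(parts) > 1 else ""
        if name in descriptors:
            raise VocabFormatError(f"duplicate descriptor row: {name!r}")
        descriptors[name] = [t.strip() for t in trees_cell.split(";") if t.strip()]
    return MeshVocabulary(descriptors=descriptors)


def write_mesh_tsv(vocab: MeshVocabulary, dest) -> None:
    """Write the simplified TSV dialect (round-trips through load_mesh_tsv)."""
    own = not hasattr(dest, "write")
    handle = Path(dest).open("w", encoding="utf-8") if own else dest
    try:
        handle.write("descriptor\ttree_numbers\n")
        for name, trees in vocab.descriptors.items():
            handle.write(f"{name}\t{';'.join(trees)}\n")
    finally:
        if own:
            handle.close()


def classify_term(
    vocab: MeshVocabulary,
    descriptor: str,
    interaction_terms: Iterable[str] | None = None,
) -> TermCategory:
    """Categorize one descriptor (total function; unknown names -> other)."""
    if interaction_terms is None:
        from .corpus import INTERACTION_TERMS

        interaction_terms = INTERACTION_TERMS
    key = norm_term(descriptor)
    if key in {norm_term(t) for t in interaction_terms}:
        return TermCategory.INTERACTION
    canon = vocab.canonical(descriptor)
    if canon is None:
        return TermCategory.OTHER
    if canon in vocab.drug_list:
        return TermCategory.DRUG
    trees = vocab.descriptors[canon]
    if any(_tree_under(t, b) for t in trees for b in PROTEIN_BRANCHES):
        return TermCategory.PROTEIN
    if any(_tree_under(t, b) for t in trees for b in PHENOMENA_BRANCHES):
        return TermCategory.PHENOMENA
    return TermCategory.OTHER


def candidate_terms(
    vocab: MeshVocabulary,
    articles: Iterable,
    categories: Iterable[TermCategory] = CANDIDATE_CATEGORIES,
    exclude_drug: str | None = None,
    interaction_terms: Iterable[str] | None = None,
) -> dict[TermCategory, set[str]]:
    """Bucket the descriptors occurring in ``articles`` by category.

    ``articles`` is normally group A of a partitioned corpus.  The query
    drug's own descriptor (``exclude_drug``) is removed from the drug
    bucket: it appears in essentially every record by construction.
    Buckets are pairwise disjoint (one category per descriptor).
    """
    wanted = set(categories)
    buckets: dict[TermCategory, set[str]] = {c: set() for c in wanted}
    seen: set[str] = set()
    exclude_key = norm_term(exclude_drug) if exclude_drug else None
    for art in articles:
        for heading in art.mesh_headings:
            key = norm_term(heading.descriptor)
            if key in seen:
                continue
            seen.add(key)
            cat = classify_term(vocab, heading.descriptor, interaction_terms)
            if cat not in wanted:
                continue
            if cat is TermCategory.DRUG and key == exclude_key:
                continue
            canon = vocab.canonical(heading.descriptor) or heading.descriptor
            buckets[cat].add(canon)
    return buckets
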