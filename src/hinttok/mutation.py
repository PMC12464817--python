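"""Point-substitution parsing and hint-token sequence augmentation.

Hint token learning (HTL) marks every mutated residue in a mutant protein
sequence by flanking it with two special tokens, ``[MUT_start]`` and
``[MUT_end]``, before tokenization.  The mutation D26E (aspartate at
position 26 replaced by glutamate) therefore appears in the augmented
sequence as ``... [MUT_start] E [MUT_end] ...`` at position 26.  The
special tokens are appended to the base vocabulary in a fixed order so
that token ids are reproducible across runs.

Conventions: mutation positions are 1-based in notation and I/O
(matching the D26E convention); internal string indexing is 0-based
half-open.  Only substitutions are supported — insertions and deletions
are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

#: The twenty standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Extended codes accepted when explicitly configured in the alphabet.
EXTENDED_AA = "XUBZ"

MUT_START = "[MUT_start]"
MUT_END = "[MUT_end]"

#: Conventional padding symbol; id 0 in the default base vocabulary.
PAD = "<pad>"

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class MutationError(ValueError):
    """Malformed mutation notation or a record violating its invariants."""


@dataclass(frozen=True, order=True)
class Mutation:
    """A single point substitution, e.g. ``Mutation(26, "D", "E")`` for D26E."""

    position: int  # 1-based residue index
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MutationError(f"position must be >= 1, got {self.position}")
        for name, aa in (("ref", self.ref), ("alt", self.alt)):
            if len(aa) != 1 or not aa.isalpha():
                raise MutationError(f"{name} must be a single letter, got {aa!r}")
        if self.ref == self.alt:
            raise MutationError(
                f"silent substitution {self.ref}{self.position}{self.alt}: ref == alt"
            )

    @property
    def notation(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"


def parse_mutation_string(s: str, alphabet: str = STANDARD_AA) -> Mutation:
    """Parse ``<ref><position><alt>`` notation such as ``"D26E"``.

    Letters are normalized to upper case and must belong to *alphabet*.
    """
    m = _MUTATION_RE.match(s.strip())
    if m is None:
        raise MutationError(f"malformed mutation string: {s!r}")
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    for aa in (ref, alt):
        if aa not in alphabet:
            raise MutationError(f"{aa!r} not in configured alphabet in {s!r}")
    return Mutation(pos, ref, alt)


def apply_mutations(wt: str, mutations: Sequence[Mutation]) -> str:
    """Apply substitutions to *wt*; each ref must match the wild type."""
    chars = list(wt)
    seen: set[int] = set()
    for mut in mutations:
        if mut.position > len(wt):
            raise MutationError(
                f"{mut.notation} beyond sequence length {len(wt)}"
            )
        if mut.position in seen:
            raise MutationError(f"duplicate mutation position {mut.position}")
        seen.add(mut.position)
        if chars[mut.position - 1] != mut.ref:
            raise MutationError(
                f"ref mismatch at position {mut.position}: expected "
                f"{mut.ref}, wild type has {chars[mut.position - 1]}"
            )
        chars[mut.position - 1] = mut.alt
    return "".join(chars)


def diff_sequences(wt: str, mutant: str, alphabet: str = STANDARD_AA) -> list[Mutation]:
    """Position-sorted substitutions turning *wt* into *mutant*.

    Sequences must have equal length (indels are unsupported) and use the
    configured alphabet.  Inverse of :func:`apply_mutations`.
    """
    wt, mutant = wt.upper(), mutant.upper()
    if len(wt) != len(mutant):
        raise MutationError(
            f"length mismatch ({len(wt)} vs {len(mutant)}): indels unsupported"
        )
    for seq, name in ((wt, "wild type"), (mutant, "mutant")):
        bad = set(seq) - set(alphabet)
        if bad:
            raise MutationError(f"illegal characters in {name}: {sorted(bad)}")
    return [
        Mutation(i + 1, a, b)
        for i, (a, b) in enumerate(zip(wt, mutant))
        if a != b
    ]


@dataclass(frozen=True)
class MutantRecord:
    """A labelled protein variant: wild type plus point substitutions."""

    record_id: str
    wt_sequence: str
    mutations: tuple[Mutation, ...]
    label: str
    mutant_sequence: str = field(default="")

    def __post_init__(self) -> None:
        muts = tuple(sorted(self.mutations, key=lambda m: m.position))
        object.__setattr__(self, "mutations", muts)
        derived = apply_mutations(self.wt_sequence, muts)
        if self.mutant_sequence and self.mutant_sequence != derived:
            raise MutationError(
                f"record {self.record_id}: mutant_sequence inconsistent with mutations"
            )
        object.__setattr__(self, "mutant_sequence", derived)

    @classmethod
    def from_mutant_sequence(
        cls,
        record_id: str,
        wt_sequence: str,
        mutant_sequence: str,
        label: str,
        alphabet: str = STANDARD_AA,
    ) -> "MutantRecord":
        muts = diff_sequences(wt_sequence, mutant_sequence, alphabet)
        return cls(record_id, wt_sequence.upper(), tuple(muts), label)

    @classmethod
    def from_notation(
        cls,
        record_id: str,
        wt_sequence: str,
        notation: str,
        label: str,
        alphabet: str = STANDARD_AA,
        sep: str = ";",
    ) -> "MutantRecord":
        """Build from semicolon-separated notation like ``"D26E;V30A"``."""
        notation = notation.strip()
        muts = (
            tuple(parse_mutation_string(tok, alphabet) for tok in notation.split(sep))
            if notation
            else ()
        )
        return cls(record_id, wt_sequence.upper(), muts, label)

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)


# ---------------------------------------------------------------------------
# Augmentation: inserting and stripping hint tokens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentedSequence:
    """A mutant sequence with hint tokens interleaved.

    ``elements`` holds one symbol per slot — a residue letter or one of the
    two hint markers.  ``residue_index_map`` gives, for each slot, the
    1-based residue position in the mutant sequence, or ``None`` for hint
    tokens.
    """

    elements: tuple[str, ...]
    residue_index_map: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if len(self.elements) != len(self.residue_index_map):
            raise MutationError("elements and residue_index_map length mismatch")

    @property
    def mutant_sequence(self) -> str:
        return "".join(
            e for e in self.elements if e not in (MUT_START, MUT_END)
        )

    @property
    def n_hint_pairs(self) -> int:
        return sum(1 for e in self.elements if e == MUT_START)


def augmented_from_elements(elements: Iterable[str]) -> AugmentedSequence:
    """Validate a symbol stream and rebuild the residue index map.

    Every ``[MUT_start]`` must be followed by exactly one residue and then
    ``[MUT_end]``; stray markers raise :class:`MutationError`.
    """
    elems = tuple(elements)
    index_map: list[Optional[int]] = []
    residue_pos = 0
    i = 0
    while i < len(elems):
        e = elems[i]
        if e == MUT_START:
            if (
                i + 2 >= len(elems)
                or elems[i + 1] in (MUT_START, MUT_END)
                or elems[i + 2] != MUT_END
            ):
                raise MutationError(f"unmatched {MUT_START} at element {i}")
            residue_pos += 1
            index_map.extend([None, residue_pos, None])
            i += 3
        elif e == MUT_END:
            raise MutationError(f"unmatched {MUT_END} at element {i}")
        else:
            residue_pos += 1
            index_map.append(residue_pos)
            i += 1
    return AugmentedSequence(elems, tuple(index_map))


def insert_hint_tokens(record: MutantRecord) -> AugmentedSequence:
    """Flank each mutated residue of the mutant sequence with hint tokens.

    Insertion proceeds right-to-left over the position-sorted mutations so
    that earlier positions never shift.
    """
    elems = list(record.mutant_sequence)
    for mut in reversed(record.mutations):
        i = mut.position - 1
        elems[i : i + 1] = [MUT_START, elems[i], MUT_END]
    return augmented_from_elements(elems)


def strip_hint_tokens(aug: AugmentedSequence) -> str:
    """Remove hint tokens, returning the plain mutant sequence."""
    # Re-validate pairing so corrupted element streams are caught.
    return augmented_from_elements(aug.elements).mutant_sequence


# ---------------------------------------------------------------------------
# Vocabulary and integer encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HintVocabulary:
    """A base symbol→id map extended with the two hint-token ids."""

    base_map: Mapping[str, int]
    mut_start_id: int
    mut_end_id: int

    @property
    def size(self) -> int:
        return len(self.base_map) + 2

    def id_of(self, symbol: str) -> int:
        if symbol == MUT_START:
            return self.mut_start_id
        if symbol == MUT_END:
            return self.mut_end_id
        return self.base_map[symbol]

    def symbol_of(self, token_id: int) -> str:
        if token_id == self.mut_start_id:
            return MUT_START
        if token_id == self.mut_end_id:
            return MUT_END
        try:
            return self._inverse[token_id]
        except KeyError:
            raise KeyError(f"unknown token id {token_id}") from None

    @property
    def _inverse(self) -> dict[int, str]:
        inv = getattr(self, "_inv_cache", None)
        if inv is None:
            inv = {v: k for k, v in self.base_map.items()}
            object.__setattr__(self, "_inv_cache", inv)
        return inv


def base_vocabulary(alphabet: str = STANDARD_AA, include_pad: bool = True) -> dict[str, int]:
    """Symbol→id map over *alphabet*, optionally with ``<pad>`` at id 0."""
    symbols = ([PAD] if include_pad else []) + list(alphabet)
    return {s: i for i, s in enumerate(symbols)}


def extend_vocabulary(base_map: Mapping[str, int]) -> HintVocabulary:
    """Append ``[MUT_start]`` then ``[MUT_end]`` after the base ids.

    Base ids must be distinct and contiguous from 0; the hint ids are then
    ``len(base_map)`` and ``len(base_map) + 1``, deterministically.
    """
    ids = sorted(base_map.values())
    if ids != list(range(len(base_map))):
        raise MutationError("base vocabulary ids must be distinct and contiguous from 0")
    for special in (MUT_START, MUT_END):
        if special in base_map:
            raise MutationError(f"{special} already present in base vocabulary")
    n = len(base_map)
    return HintVocabulary(dict(base_map), n, n + 1)


def encode(
    aug: AugmentedSequence,
    vocab: HintVocabulary,
    unknown_id: Optional[int] = None,
) -> list[int]:
    """Map augmented-sequence symbols to integer ids.

    Unknown symbols raise ``KeyError`` unless *unknown_id* is given.
    """
    ids: list[int] = []
    for e in aug.elements:
        try:
            ids.append(vocab.id_of(e))
        except KeyError:
            if unknown_id is None:
                raise KeyError(f"symbol {e!r} not in vocabulary") from None
            ids.append(unknown_id)
    return ids


def decode(ids: Sequence[int], vocab: HintVocabulary) -> AugmentedSequence:
    """Inverse of :func:`encode`; rebuilds the augmented sequence."""
    return augmented_from_elements(vocab.symbol_of(i) for i in ids)


def tokenize_record(
    record: MutantRecord,
    vocab: HintVocabulary,
    htl: bool = True,
    max_len: Optional[int] = None,
) -> tuple[AugmentedSequence, list[int]]:
    """Full encoding path for one record, with or without hint tokens.

    The control path (``htl=False``) tokenizes the plain mutant sequence,
    identical to wild-type input except for the substituted residues.
    """
    if htl:
        aug = insert_hint_tokens(record)
    else:
        aug = augmented_from_elements(record.mutant_sequence)
    if max_len is not None:
        aug = truncate_augmented(aug, max_len)
    return aug, encode(aug, vocab)


# ---------------------------------------------------------------------------
# Truncation and text serialization
# ---------------------------------------------------------------------------

def truncate_augmented(aug: AugmentedSequence, max_len: int) -> AugmentedSequence:
    """Truncate to *max_len* elements with a window centred on the first
    mutation, never splitting a hint pair.

    A hint pair whose three slots would straddle a window boundary is
    dropped whole; the pair around the first mutation always survives.
    """
    n = len(aug.elements)
    if n <= max_len:
        return aug
    if max_len < 3:
        raise MutationError("max_len must be >= 3 to preserve a hint pair")
    starts = [i for i, e in enumerate(aug.elements) if e == MUT_START]
    centre = starts[0] + 1 if starts else n // 2
    lo = max(0, min(centre - max_len // 2, n - max_len))
    hi = lo + max_len
    # Shift boundaries off the interior of any hint pair.
    spans = [(s, s + 2) for s in starts]
    for s, e in spans:
        if s < lo <= e:
            lo = e + 1
        if s <= hi - 1 < e:
            hi = s
    elems = aug.elements[lo:hi]
    out = augmented_from_elements(elems)
    # Re-offset the residue map to mutant-sequence coordinates.
    offset = sum(
        1 for i in range(lo) if aug.elements[i] not in (MUT_START, MUT_END)
    )
    shifted = tuple(
        None if p is None else p + offset for p in out.residue_index_map
    )
    return AugmentedSequence(out.elements, shifted)


def serialize_augmented(aug: AugmentedSequence, spaced: bool = True) -> str:
    """Render the augmented sequence as text with literal hint markers.

    ``spaced=True`` emits the whitespace-separated dialect expected by
    models that tokenize residues individually; ``spaced=False`` emits a
    compact form.
    """
    return (" " if spaced else "").join(aug.elements)


def parse_augmented(text: str) -> AugmentedSequence:
    """Parse either serialization dialect back into an augmented sequence."""
    tokens: list[str] = []
    if " " in text.strip():
        tokens = text.split()
    else:
        i = 0
        while i < len(text):
            if text.startswith(MUT_START, i):
                tokens.append(MUT_START)
                i += len(MUT_START)
            elif text.startswith(MUT_END, i):
                tokens.append(MUT_END)
                i += len(MUT_END)
            else:
                tokens.append(text[i])
                i += 1
    return augmented_from_elements(tokens)
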