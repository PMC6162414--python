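"""Reading, validation and shuffling of transcript and miRNA sequences.

All sequences are held internally as RNA over the strict alphabet
``{A, C, G, U}``. DNA-style input (``T``) is accepted and converted, because
the downstream scanners operate on spliced transcripts. IUPAC ambiguity
codes are rejected outright: silently randomising an ``N`` would make the
permutation null irreproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

RNA_ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}

# uint8 lookup: ASCII byte -> base index, 255 marks an invalid character
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _CODE_LUT[ord(_b)] = _i
_CHAR_LUT = np.frombuffer(RNA_ALPHABET.encode("ascii"), dtype=np.uint8)


class SequenceError(ValueError):
    """Raised for malformed or non-{A,C,G,U} sequence input."""


@dataclass(frozen=True)
class NamedSequence:
    """A named RNA sequence (5'->3') over the strict {A,C,G,U} alphabet."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise SequenceError("sequence name must be non-empty")
        if not self.sequence:
            raise SequenceError(f"sequence {self.name!r} is empty")
        bad = set(self.sequence) - set(RNA_ALPHABET)
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence, start=1) if c in bad
            )
            raise SequenceError(
                f"sequence {self.name!r}: invalid character "
                f"{self.sequence[pos - 1]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str) -> str:
    """Normalize raw sequence text to strict RNA.

    Uppercases, strips all whitespace and maps T->U. Any remaining character
    outside {A,C,G,U} (including IUPAC ambiguity codes) raises
    :class:`SequenceError` naming the 1-based offending position.
    """
    if raw is None or raw == "":
        raise SequenceError("empty sequence")
    cleaned = "".join(raw.split()).upper().replace("T", "U")
    if not cleaned:
        raise SequenceError("sequence contains only whitespace")
    for i, c in enumerate(cleaned, start=1):
        if c not in _BASE_INDEX:
            raise SequenceError(f"invalid character {c!r} at position {i}")
    return cleaned


def read_fasta(path) -> list[NamedSequence]:
    """Read a (multi-record) FASTA file into normalized :class:`NamedSequence`.

    Record order is preserved. Duplicate record names, empty files and
    per-record alphabet violations are reported with the record index.
    """
    records = []
    seen: set[str] = set()
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise SequenceError(f"{path}: record {idx} has an empty header")
        if rec.id in seen:
            raise SequenceError(
                f"{path}: duplicate record name {rec.id!r} (record {idx})"
            )
        seen.add(rec.id)
        try:
            seq = normalize_sequence(str(rec.seq))
        except SequenceError as exc:
            raise SequenceError(
                f"{path}: record {idx} ({rec.id!r}): {exc}"
            ) from exc
        records.append(NamedSequence(rec.id, seq))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def read_name_sequence_tsv(path) -> list[NamedSequence]:
    """Read a two-column ``name<TAB>sequence`` table (``#`` comments allowed)."""
    records = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SequenceError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            name, raw = parts
            if name in seen:
                raise SequenceError(f"{path}:{lineno}: duplicate name {name!r}")
            seen.add(name)
            try:
                records.append(NamedSequence(name, normalize_sequence(raw)))
            except SequenceError as exc:
                raise SequenceError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        raise SequenceError(f"{path}: no sequences found")
    return records


def encode(sequence: str) -> np.ndarray:
    """Encode a strict-RNA string as a uint8 index array (A=0,C=1,G=2,U=3)."""
    codes = _CODE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) == 255:
        bad = int(np.argmax(codes == 255))
        raise SequenceError(
            f"invalid character {sequence[bad]!r} at position {bad + 1}"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _CHAR_LUT[codes].tobytes().decode("ascii")


def shuffle_sequence(
    seq: NamedSequence,
    rng_seed: int,
    *,
    preserve_dinucleotides: bool = False,
) -> NamedSequence:
    """Return a random permutation of ``seq`` with identical base composition.

    The default null model permutes mononucleotides uniformly at random.
    ``preserve_dinucleotides=True`` switches to an Altschul-Erickson style
    shuffle that additionally conserves the dinucleotide counts (a stricter
    optional null, off by default).

    Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    if preserve_dinucleotides:
        shuffled = _dinucleotide_shuffle(seq.sequence, rng)
    else:
        shuffled = decode(rng.permutation(encode(seq.sequence)))
    return NamedSequence(f"{seq.name}|shuffle", shuffled)


def _dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson dinucleotide-preserving shuffle.

    Treats the sequence as an Eulerian walk on the graph whose vertices are
    bases and whose edges are the observed dinucleotide steps; samples a
    uniform random Eulerian walk with the same start and end vertex by the
    last-edge/arborescence construction.
    """
    if len(sequence) < 3 or len(set(sequence)) == 1:
        return sequence
    first, last = sequence[0], sequence[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)

    vertices = sorted(edges.keys() | {last})
    while True:
        # pick a candidate last exit edge for every vertex except the end
        last_edge = {}
        for v in vertices:
            if v == last or not edges.get(v):
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        # the chosen last edges must form an arborescence into `last`
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    out_lists: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        order = rng.permutation(len(rest))
        shuffled = [rest[i] for i in order]
        if v in last_edge:
            shuffled.append(last_edge[v])
        out_lists[v] = shuffled

    walk = [first]
    pos = {v: 0 for v in out_lists}
    cur = first
    for _ in range(len(sequence) - 1):
        nxt = out_lists[cur][pos[cur]]
        pos[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)
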