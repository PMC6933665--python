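"""Sequence and structure I/O.

RNA sequences are read from FASTA (via Biopython) or raw text and validated
against the alphabet {A, C, G, U}; DNA-style T is silently mapped to U.
Secondary structures travel as *pair maps*: symmetric ``dict[int, int]`` over
1-based positions, containing both directions of every base pair and no
self-entries.  Three text formats are supported:

* extended dot-bracket, with bracket layers ``()``, ``[]``, ``{}``, ``<>``
  and then ``Aa`` .. ``Zz`` for pseudoknotted (crossing) pairs;
* CT (connectivity table, 6 columns with a count header);
* bpseq (3 columns: position, base, partner-or-0).

All positions are 1-based inclusive; conversion to Python indices happens
only inside this module.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

#: Bracket layers for pseudoknotted dot-bracket strings, in assignment order.
_LAYERS: List[Tuple[str, str]] = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")] + [
    (chr(ord("A") + t), chr(ord("a") + t)) for t in range(26)
]
_OPEN = {o: idx for idx, (o, _) in enumerate(_LAYERS)}
_CLOSE = {c: idx for idx, (_, c) in enumerate(_LAYERS)}

PairMap = Dict[int, int]


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence with a 1-based coordinate convention."""

    id: str
    residues: str

    @property
    def n(self) -> int:
        return len(self.residues)

    def base(self, p: int) -> str:
        """Residue at 1-based position ``p``."""
        if not 1 <= p <= self.n:
            raise IndexError(f"position {p} outside 1..{self.n}")
        return self.residues[p - 1]

    def __len__(self) -> int:
        return self.n


def validate_sequence(raw: str, id: str = "seq") -> RnaSequence:
    """Normalize and validate raw sequence text.

    Whitespace is stripped, letters are uppercased and T becomes U.  Any
    other character is a hard error naming the offending (post-stripping,
    1-based) position.
    """
    cleaned = "".join(raw.split()).upper().replace("T", "U")
    if not cleaned:
        raise ValueError(f"sequence {id!r} is empty")
    for pos, ch in enumerate(cleaned, start=1):
        if ch not in RNA_ALPHABET:
            raise ValueError(
                f"sequence {id!r}: invalid residue {ch!r} at position {pos}"
            )
    return RnaSequence(id=id, residues=cleaned)


def read_fasta(path) -> List[RnaSequence]:
    """Read a (multi-record) FASTA file into validated sequences, in order."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: record {rec.id!r} has no sequence")
        out.append(validate_sequence(str(rec.seq), id=rec.id))
    return out


def write_fasta(seqs: Iterable[RnaSequence]) -> str:
    buf = io.StringIO()
    for s in seqs:
        buf.write(f">{s.id}\n{s.residues}\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# pair maps


def check_pair_map(pairs: PairMap, n: int) -> None:
    """Validate that ``pairs`` is a symmetric involution over 1..n."""
    for p, q in pairs.items():
        if not (1 <= p <= n and 1 <= q <= n):
            raise ValueError(f"pair ({p},{q}) outside 1..{n}")
        if p == q:
            raise ValueError(f"position {p} paired with itself")
        if pairs.get(q) != p:
            raise ValueError(f"pair map is not an involution at ({p},{q})")


def pairs_as_tuples(pairs: PairMap) -> List[Tuple[int, int]]:
    """Unordered pairs as sorted (p, q) tuples with p < q."""
    return sorted((p, q) for p, q in pairs.items() if p < q)


# ---------------------------------------------------------------------------
# parsing


def parse_structure(text: str, format: str, n: int | None = None) -> PairMap:
    """Parse a structure string/record into a pair map.

    ``format`` is one of ``dotbracket``, ``ct``, ``bpseq``.  If ``n`` is
    given the parsed structure must describe exactly that many positions.
    """
    if format == "dotbracket":
        pairs, length = _parse_dotbracket(text)
    elif format == "ct":
        pairs, length = _parse_ct(text)
    elif format == "bpseq":
        pairs, length = _parse_bpseq(text)
    else:
        raise ValueError(f"unknown structure format {format!r}")
    if n is not None and length != n:
        raise ValueError(f"structure has {length} positions, expected {n}")
    check_pair_map(pairs, length)
    return pairs


def _parse_dotbracket(text: str) -> Tuple[PairMap, int]:
    s = text.strip()
    stacks: Dict[int, List[int]] = {}
    pairs: PairMap = {}
    for pos, ch in enumerate(s, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks.setdefault(_OPEN[ch], []).append(pos)
        elif ch in _CLOSE:
            layer = _CLOSE[ch]
            if not stacks.get(layer):
                raise ValueError(f"unbalanced {ch!r} at position {pos}")
            p = stacks[layer].pop()
            pairs[p] = pos
            pairs[pos] = p
        else:
            raise ValueError(f"invalid structure character {ch!r} at position {pos}")
    for layer, stack in stacks.items():
        if stack:
            o = _LAYERS[layer][0]
            raise ValueError(f"unbalanced {o!r} opened at position {stack[-1]}")
    return pairs, len(s)


def _structure_lines(text: str) -> List[List[str]]:
    rows = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            rows.append(line.split())
    return rows


def _parse_ct(text: str) -> Tuple[PairMap, int]:
    rows = _structure_lines(text)
    if not rows:
        raise ValueError("empty CT record")
    n = int(rows[0][0])
    body = rows[1:]
    if len(body) != n:
        raise ValueError(f"CT header says {n} bases, found {len(body)} rows")
    return _pairs_from_partner_column(((int(r[0]), int(r[4])) for r in body), n), n


def _parse_bpseq(text: str) -> Tuple[PairMap, int]:
    rows = _structure_lines(text)
    if not rows:
        raise ValueError("empty bpseq record")
    n = len(rows)
    return _pairs_from_partner_column(((int(r[0]), int(r[2])) for r in rows), n), n


def _pairs_from_partner_column(items, n: int) -> PairMap:
    partner = {}
    for p, q in items:
        if not 1 <= p <= n:
            raise ValueError(f"index {p} outside 1..{n}")
        if p in partner:
            raise ValueError(f"duplicate index {p}")
        partner[p] = q
    if len(partner) != n:
        raise ValueError("missing position rows")
    pairs: PairMap = {}
    for p, q in partner.items():
        if q == 0:
            continue
        if not 1 <= q <= n:
            raise ValueError(f"partner {q} of position {p} outside 1..{n}")
        if partner.get(q) != p:
            raise ValueError(f"partner mismatch: {p}->{q} but {q}->{partner.get(q)}")
        pairs[p] = q
    return pairs


# ---------------------------------------------------------------------------
# writing


def write_structure(seq: RnaSequence, pairs: PairMap, format: str) -> str:
    """Render a pair map in the requested format; round-trips via parse."""
    check_pair_map(pairs, seq.n)
    if format == "dotbracket":
        return _write_dotbracket(pairs, seq.n)
    if format == "ct":
        return _write_ct(seq, pairs)
    if format == "bpseq":
        return _write_bpseq(seq, pairs)
    raise ValueError(f"unknown structure format {format!r}")


def _crosses(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    (p, q), (r, s) = a, b
    return p < r < q < s or r < p < s < q


def _write_dotbracket(pairs: PairMap, n: int) -> str:
    # first-fit greedy: each pair goes to the lowest layer where it crosses
    # nothing already placed there, so each layer is properly nested
    layers: List[List[Tuple[int, int]]] = []
    chars = ["."] * n
    for pair in pairs_as_tuples(pairs):
        for idx, placed in enumerate(layers):
            if not any(_crosses(pair, other) for other in placed):
                placed.append(pair)
                break
        else:
            idx = len(layers)
            if idx >= len(_LAYERS):
                raise ValueError("more crossing classes than available bracket layers")
            layers.append([pair])
        o, c = _LAYERS[idx]
        chars[pair[0] - 1] = o
        chars[pair[1] - 1] = c
    return "".join(chars)


def _write_ct(seq: RnaSequence, pairs: PairMap) -> str:
    lines = [f"{seq.n}\t{seq.id}"]
    for p in range(1, seq.n + 1):
        nxt = p + 1 if p < seq.n else 0
        lines.append(
            f"{p}\t{seq.base(p)}\t{p - 1}\t{nxt}\t{pairs.get(p, 0)}\t{p}"
        )
    return "\n".join(lines) + "\n"


def _write_bpseq(seq: RnaSequence, pairs: PairMap) -> str:
    return "".join(
        f"{p} {seq.base(p)} {pairs.get(p, 0)}\n" for p in range(1, seq.n + 1)
    )
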