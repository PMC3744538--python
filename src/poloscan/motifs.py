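"""Degenerate linear-motif compilation and exhaustive proteome scanning.

Kinase consensus sites — e.g. the Plk1 kinase-domain phosphorylation
consensus ``[E/D]X[pS/pT][I/L/V/M]X[E]`` — and phosphopeptide docking
signatures — the polo-box-domain (PBD) recognition motif
``S-[pS/pT]-[P/X]`` — are short degenerate patterns over the 20-letter
amino-acid alphabet with one designated phosphoacceptor position (the
serine or threonine that receives the phosphate, marked by a ``p``
prefix in the notation).

This module compiles the bracket notation into positional
allowed-residue sets (:class:`MotifPattern`), slides a window of motif
length over protein sequences one residue at a time, and scores every
window by a similarity index: the fraction of motif positions whose
window residue is allowed.  Wildcard positions (``X``) always match, so
for the 6-position kinase consensus the 0.80 threshold admits exactly
one mismatch among the constrained non-phosphoacceptor positions.  The
phosphoacceptor itself is a hard constraint: a window is only ever
reported as a hit when that residue matches exactly, whatever the
threshold.

An optional substitution mode relaxes the per-position test from
identity to "positive substitution score against at least one allowed
residue" (BLOSUM62 by default), which approximates how a local-alignment
search with that matrix would treat conservative replacements.  Because
the BLOSUM62 diagonal is positive, every identity-mode match is also a
substitution-mode match, so the substitution-mode hit set contains the
identity-mode hit set at any threshold.

Conventions
-----------
* Coordinates are 1-based inclusive everywhere.
* Ambiguity codes (``B``, ``Z``, ``U``, ``X``) and stop (``*``) are legal
  in input sequences but match only wildcard positions in identity mode.
* All qualifying windows are reported, including overlapping ones.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, MatrixError, MotifNotationError, WindowLengthError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
PHOSPHOACCEPTORS = frozenset("ST")

#: Allowed-residue set of a wildcard position (the full alphabet).
FULL_ALPHABET = frozenset(AMINO_ACIDS)

KINASE_CONSENSUS = "[E/D]X[pS/pT][I/L/V/M]X[E]"
PBD_CONSENSUS = "S-[pS/pT]-[P/X]"


@dataclass(frozen=True)
class MotifPattern:
    """A positional degenerate motif with one phosphoacceptor position.

    Parameters
    ----------
    name:
        Short label carried into every hit.
    positions:
        Ordered allowed-residue sets; a wildcard position is the full
        20-letter alphabet.
    phospho_index:
        1-based position of the phosphoacceptor; its allowed set must be
        a non-empty subset of ``{S, T}``.
    """

    name: str
    positions: tuple[frozenset, ...]
    phospho_index: int

    def __post_init__(self):
        if len(self.positions) < 2:
            raise MotifNotationError("a motif needs at least 2 positions")
        if not 1 <= self.phospho_index <= len(self.positions):
            raise MotifNotationError(
                f"phospho_index {self.phospho_index} outside 1..{len(self.positions)}"
            )
        for i, allowed in enumerate(self.positions, start=1):
            if not allowed:
                raise MotifNotationError(f"empty allowed set at position {i}")
            if not allowed <= AA_SET:
                bad = "".join(sorted(allowed - AA_SET))
                raise MotifNotationError(f"unknown residue(s) {bad!r} at position {i}")
        acceptor = self.positions[self.phospho_index - 1]
        if not acceptor <= PHOSPHOACCEPTORS:
            raise MotifNotationError(
                "phosphoacceptor set must be a subset of {S, T}, got "
                + "".join(sorted(acceptor))
            )

    @property
    def length(self) -> int:
        return len(self.positions)

    def is_wildcard(self, i: int) -> bool:
        """True if 0-based position *i* matches any residue."""
        return self.positions[i] == FULL_ALPHABET


@dataclass(frozen=True)
class MotifHit:
    """One scored window match of a motif in a protein.

    ``start`` is the 1-based inclusive window position;
    ``phospho_position`` is the absolute 1-based position of the
    phosphoacceptor residue (always S or T in a reported hit);
    ``similarity`` is matched positions divided by motif length.
    """

    protein_id: str
    motif_name: str
    start: int
    window: str
    similarity: float
    phospho_position: int
    per_position_match: tuple[bool, ...] = field(repr=False, default=())

    @property
    def end(self) -> int:
        return self.start + len(self.window) - 1


def _parse_token(raw: str, bracket_x_wildcard: bool):
    """Return (allowed_set, is_phospho) for one notation token."""
    alternatives = raw.split("/")
    allowed: set[str] = set()
    phospho = False
    wildcard = False
    for alt in alternatives:
        if not alt:
            raise MotifNotationError(f"empty alternative in token {raw!r}")
        if alt.startswith("p") and len(alt) == 2:
            phospho = True
            alt = alt[1]
        if len(alt) != 1:
            raise MotifNotationError(f"malformed alternative {alt!r} in token {raw!r}")
        if alt == "X":
            if bracket_x_wildcard or len(alternatives) == 1:
                wildcard = True
            # in strict mode a bracketed X alternative is dropped
            continue
        if alt not in AA_SET:
            raise MotifNotationError(f"unknown residue {alt!r} in token {raw!r}")
        allowed.add(alt)
    if wildcard:
        return FULL_ALPHABET, phospho
    if not allowed:
        raise MotifNotationError(f"token {raw!r} admits no residue")
    return frozenset(allowed), phospho


def compile_motif(
    notation: str, name: str | None = None, bracket_x_wildcard: bool = True
) -> MotifPattern:
    """Compile bracket notation into a :class:`MotifPattern`.

    Tokens are single residue letters, the wildcard ``X``, or bracketed
    alternations like ``[E/D]``; a ``p`` prefix marks the (single)
    phosphoacceptor token; ``-`` separators are ignored.  Inside a
    bracket a bare ``X`` alternative (as in ``[P/X]``) widens the
    position to the full alphabet unless ``bracket_x_wildcard`` is
    False, in which case it is dropped — the "strict" reading of the PBD
    motif's third position, which then requires proline.

    >>> m = compile_motif("[E/D]X[pS/pT][I/L/V/M]X[E]")
    >>> m.length, m.phospho_index
    (6, 3)
    """
    if name is None:
        name = notation
    s = notation.replace("-", "").replace(" ", "")
    if not s:
        raise MotifNotationError("empty motif notation")
    raw_tokens: list[str] = []
    i = 0
    while i < len(s):
        if s[i] == "[":
            j = s.find("]", i)
            if j < 0:
                raise MotifNotationError(f"unbalanced '[' in {notation!r}")
            raw_tokens.append(s[i + 1 : j])
            i = j + 1
        elif s[i] == "]":
            raise MotifNotationError(f"unbalanced ']' in {notation!r}")
        elif s[i] == "p":
            if i + 1 >= len(s):
                raise MotifNotationError("dangling 'p' prefix")
            raw_tokens.append(s[i : i + 2])
            i += 2
        else:
            raw_tokens.append(s[i])
            i += 1

    positions: list[frozenset] = []
    phospho_index = None
    for pos, raw in enumerate(raw_tokens, start=1):
        allowed, phospho = _parse_token(raw, bracket_x_wildcard)
        positions.append(allowed)
        if phospho:
            if phospho_index is not None:
                raise MotifNotationError("multiple phosphoacceptor tokens")
            phospho_index = pos
    if phospho_index is None:
        raise MotifNotationError("no phosphoacceptor token (missing 'p' prefix)")
    return MotifPattern(name=name, positions=tuple(positions), phospho_index=phospho_index)


def per_position_matches(window: str, motif: MotifPattern) -> list[bool]:
    """Identity-mode per-position match vector for one window."""
    if len(window) != motif.length:
        raise WindowLengthError(
            f"window length {len(window)} != motif length {motif.length}"
        )
    return [
        allowed == FULL_ALPHABET or residue in allowed
        for residue, allowed in zip(window, motif.positions)
    ]


def similarity_index(window: str, motif: MotifPattern) -> float:
    """Fraction of motif positions matched by *window* (identity mode).

    Wildcard positions always count as matched; non-standard letters
    (B, Z, U, X, ``*``) match only wildcards.  The phosphoacceptor is
    scored like any other position here — the hard constraint on it is
    applied by :func:`scan_protein`, not by the score.
    """
    matches = per_position_matches(window, motif)
    return sum(matches) / motif.length


@functools.lru_cache(maxsize=1)
def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def _matrix_allowed(allowed: frozenset, matrix) -> frozenset:
    """Residues of the matrix alphabet scoring > 0 against any allowed residue."""
    if allowed == FULL_ALPHABET:
        return FULL_ALPHABET
    return frozenset(
        c
        for c in matrix.alphabet
        if max(matrix[c, r] for r in allowed) > 0
    )


def substitution_similarity(window: str, motif: MotifPattern, matrix=None) -> float:
    """Similarity under a substitution matrix (BLOSUM62 by default).

    A position counts as matched iff the matrix score between the window
    residue and at least one allowed residue is positive; wildcards
    always match.  Since the BLOSUM62 diagonal is positive this is never
    below :func:`similarity_index` on the same window.
    """
    if len(window) != motif.length:
        raise WindowLengthError(
            f"window length {len(window)} != motif length {motif.length}"
        )
    if matrix is None:
        matrix = _blosum62()
    alphabet = set(matrix.alphabet)
    matched = 0
    for residue, allowed in zip(window, motif.positions):
        if allowed == FULL_ALPHABET:
            matched += 1
            continue
        if residue not in alphabet:
            raise MatrixError(f"residue {residue!r} absent from substitution matrix")
        if max(matrix[residue, r] for r in allowed) > 0:
            matched += 1
    return matched / motif.length


def _coerce_record(record) -> tuple[str, str]:
    if isinstance(record, tuple):
        pid, seq = record
    else:
        pid, seq = record.id, record.seq
    return str(pid), str(seq)


def _match_table(positions: tuple[frozenset, ...]) -> np.ndarray:
    """Boolean lookup table (motif position, byte) -> matched."""
    tab = np.zeros((len(positions), 256), dtype=bool)
    for i, allowed in enumerate(positions):
        if allowed == FULL_ALPHABET:
            tab[i, :] = True
        else:
            for r in allowed:
                tab[i, ord(r)] = True
    return tab


@functools.lru_cache(maxsize=64)
def _cached_table(motif: MotifPattern, mode: str) -> np.ndarray:
    if mode == "identity":
        return _match_table(motif.positions)
    positions = tuple(_matrix_allowed(a, _blosum62()) for a in motif.positions)
    return _match_table(positions)


def matches_required(motif_length: int, min_similarity: float) -> int:
    """Smallest match count whose similarity reaches *min_similarity*."""
    return max(0, math.ceil(min_similarity * motif_length - 1e-9))


def scan_protein(
    record,
    motif: MotifPattern,
    min_similarity: float = 0.8,
    mode: str = "identity",
    matrix=None,
) -> list[MotifHit]:
    """Scan one protein; return all qualifying windows sorted by start.

    A window is a hit iff (a) the phosphoacceptor residue matches the
    motif's acceptor set exactly, in either mode, and (b) its similarity
    reaches *min_similarity*.  Sequences shorter than the motif yield an
    empty list.  *record* is anything with ``id``/``seq`` attributes or
    an ``(id, seq)`` tuple.
    """
    if not 0.0 <= min_similarity <= 1.0:
        raise DomainError(f"min_similarity {min_similarity} outside [0, 1]")
    if mode not in ("identity", "substitution"):
        raise DomainError(f"unknown scan mode {mode!r}")
    pid, seq = _coerce_record(record)
    ell = motif.length
    n_windows = len(seq) - ell + 1
    if n_windows <= 0:
        return []

    if mode == "substitution":
        if matrix is None:
            tab = _cached_table(motif, "substitution")
            alphabet = set(_blosum62().alphabet)
        else:
            tab = _match_table(
                tuple(_matrix_allowed(a, matrix) for a in motif.positions)
            )
            alphabet = set(matrix.alphabet)
        bad = set(seq) - alphabet
        if bad:
            raise MatrixError(
                "residue(s) absent from substitution matrix: "
                + "".join(sorted(bad))
            )
    else:
        tab = _cached_table(motif, "identity")

    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    counts = np.zeros(n_windows, dtype=np.int32)
    for i in range(ell):
        counts += tab[i, codes[i : i + n_windows]]

    # hard phosphoacceptor constraint: exact identity in both modes
    pi = motif.phospho_index - 1
    acceptor_ok = np.zeros(n_windows, dtype=bool)
    for r in motif.positions[pi]:
        acceptor_ok |= codes[pi : pi + n_windows] == ord(r)

    needed = matches_required(ell, min_similarity)
    hits = []
    for s in np.nonzero(acceptor_ok & (counts >= needed))[0]:
        s = int(s)
        window = seq[s : s + ell]
        pm = tuple(bool(tab[i, codes[s + i]]) for i in range(ell))
        hits.append(
            MotifHit(
                protein_id=pid,
                motif_name=motif.name,
                start=s + 1,
                window=window,
                similarity=int(counts[s]) / ell,
                phospho_position=s + motif.phospho_index,
                per_position_match=pm,
            )
        )
    return hits


@dataclass
class ScanResult:
    """Hits of one motif over a proteome, grouped by protein."""

    motif: MotifPattern
    mode: str
    min_similarity: float
    hits: list[MotifHit]
    proteins_scanned: int

    @property
    def hit_proteins(self) -> set[str]:
        return {h.protein_id for h in self.hits}

    @property
    def best_similarity(self) -> dict[str, float]:
        best: dict[str, float] = {}
        for h in self.hits:
            if h.similarity > best.get(h.protein_id, -1.0):
                best[h.protein_id] = h.similarity
        return best

    def hits_by_protein(self) -> dict[str, list[MotifHit]]:
        grouped: dict[str, list[MotifHit]] = {}
        for h in self.hits:
            grouped.setdefault(h.protein_id, []).append(h)
        return grouped

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "protein_id": h.protein_id,
                    "motif_name": h.motif_name,
                    "start": h.start,
                    "end": h.end,
                    "window": h.window,
                    "phospho_position": h.phospho_position,
                    "similarity": h.similarity,
                    "mode": self.mode,
                }
                for h in self.hits
            ],
            columns=[
                "protein_id",
                "motif_name",
                "start",
                "end",
                "window",
                "phospho_position",
                "similarity",
                "mode",
            ],
        )


def scan_proteome(
    proteome,
    motif: MotifPattern,
    min_similarity: float = 0.8,
    mode: str = "identity",
    matrix=None,
) -> ScanResult:
    """Concatenate :func:`scan_protein` over all records (unique ids)."""
    seen: set[str] = set()
    hits: list[MotifHit] = []
    count = 0
    for record in proteome:
        pid, _ = _coerce_record(record)
        if pid in seen:
            raise DomainError(f"duplicate protein identifier {pid!r}")
        seen.add(pid)
        count += 1
        hits.extend(scan_protein(record, motif, min_similarity, mode, matrix))
    return ScanResult(
        motif=motif,
        mode=mode,
        min_similarity=min_similarity,
        hits=hits,
        proteins_scanned=count,
    )
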