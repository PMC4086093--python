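"""Input/output: FASTA, pattern files, Phylip distance matrices, Newick trees.

FASTA parsing is delegated to Bio.SeqIO; the Phylip and Newick writers emit
the relaxed dialects that modern tree tools read (full space-free names
rather than strict 10-character fields).
"""

from __future__ import annotations

import io
import logging
import os

import numpy as np
from Bio import SeqIO

from ._types import DNA, PROTEIN, Alphabet, DistanceMatrix, Sequence
from .errors import InputFormatError
from .patterns import PatternSet, parse_pattern

logger = logging.getLogger(__name__)

_STRIP = str.maketrans("", "", "-.*")


def _open_text(source, mode="r"):
    """Accept a path or an open text handle; return (handle, should_close)."""
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode), True
    return source, False


def read_fasta(source) -> list:
    """Read a multi-FASTA file or handle into a list of :class:`Sequence`.

    Residues are uppercased; gap characters ('-', '.') and stop codons ('*')
    are stripped — the downstream methods are alignment-free, so alignment
    decoration is noise. Duplicate names are uniquified by appending
    ``_2``, ``_3``, ... with a warning.
    """
    handle, close = _open_text(source)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    except ValueError as exc:
        raise InputFormatError(f"not valid FASTA: {exc}") from exc
    finally:
        if close:
            handle.close()
    if not records:
        raise InputFormatError("no FASTA records found in input")
    seen: dict = {}
    seqs = []
    for rec in records:
        name = rec.id
        if not name:
            raise InputFormatError("FASTA record with empty header")
        residues = str(rec.seq).upper().translate(_STRIP)
        if not residues:
            raise InputFormatError(f"empty sequence: {name}")
        if name in seen:
            count = seen[name]
            while True:
                count += 1
                unique = f"{name}_{count}"
                if unique not in seen:
                    break
            seen[name] = count
            logger.warning("duplicate sequence name %r renamed to %r", name, unique)
            name = unique
        seen[name] = seen.get(name, 1)
        seqs.append(Sequence(name, residues))
    return seqs


def write_fasta(seqs, path=None, width: int = 70) -> str:
    """Serialize sequences as FASTA; write to ``path`` if given."""
    chunks = []
    for s in seqs:
        chunks.append(f">{s.name}\n")
        for i in range(0, len(s.residues), width):
            chunks.append(s.residues[i : i + width] + "\n")
    text = "".join(chunks)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def detect_alphabet(seqs) -> Alphabet:
    """Classify input as DNA or protein by residue composition.

    DNA if at least 95% of residues (ignoring the ambiguity codes N and X)
    are nucleotides; a CLI flag can override the guess.
    """
    if not seqs:
        raise InputFormatError("cannot detect alphabet of an empty sequence set")
    acgt = total = 0
    for s in seqs:
        for ch in s.residues:
            if ch in ("N", "X"):
                continue
            total += 1
            if ch in DNA.symbols:
                acgt += 1
    if total == 0 or acgt / total >= 0.95:
        return DNA
    return PROTEIN


def _safe_name(name: str) -> str:
    return name.replace(" ", "_")


def write_phylip(m: DistanceMatrix, path=None) -> str:
    """Serialize a distance matrix in relaxed Phylip format.

    One row per sequence: the space-free name padded to at least 10
    characters, then n distances with 6 decimal places.
    """
    names = [_safe_name(n) for n in m.names]
    if len(set(names)) != len(names):
        raise InputFormatError("duplicate names after space replacement")
    lines = [str(m.n)]
    for name, row in zip(names, m.values):
        vals = " ".join(f"{v:.6f}" for v in row)
        lines.append(f"{name:<10s} {vals}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_phylip(source) -> DistanceMatrix:
    """Read a relaxed Phylip square distance matrix."""
    handle, close = _open_text(source)
    try:
        lines = [ln.rstrip() for ln in handle if ln.strip()]
    finally:
        if close:
            handle.close()
    if not lines:
        raise InputFormatError("empty Phylip input")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise InputFormatError("first Phylip line must be the sequence count") from exc
    if len(lines) != n + 1:
        raise InputFormatError(f"expected {n} matrix rows, found {len(lines) - 1}")
    names, rows = [], []
    for ln in lines[1:]:
        fields = ln.split()
        if len(fields) != n + 1:
            raise InputFormatError(f"malformed Phylip row: {ln!r}")
        names.append(fields[0])
        rows.append([float(v) for v in fields[1:]])
    values = np.asarray(rows)
    # Symmetrize away the 1e-6 rounding of the text format.
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(names, values)


def read_patterns(source) -> PatternSet:
    """Read a pattern file: one 0/1 mask per line, '#' comments allowed.

    Patterns may differ in weight and length (unlike the random generator,
    which produces a homogeneous set).
    """
    handle, close = _open_text(source)
    try:
        lines = list(handle)
    finally:
        if close:
            handle.close()
    pats = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not set(line) <= {"0", "1"}:
            raise InputFormatError(f"invalid pattern character at line {lineno}")
        try:
            pats.append(parse_pattern(line))
        except InputFormatError as exc:
            raise InputFormatError(f"line {lineno}: {exc}") from exc
    if not pats:
        raise InputFormatError("no patterns found in input")
    return PatternSet(pats)


def write_patterns(ps: PatternSet, path=None) -> str:
    """Serialize a pattern set, one mask per line."""
    text = "\n".join(ps.masks()) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_newick(tree, path=None) -> str:
    """Serialize a tree (see :mod:`afdist.njtree`) as a Newick string."""

    def render(node) -> str:
        if node.is_leaf():
            label = _safe_name(node.name)
        else:
            label = "(" + ",".join(render(c) for c in node.children) + ")"
        if node.length is None:
            return label
        return f"{label}:{node.length:.6f}"

    text = render(tree) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
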