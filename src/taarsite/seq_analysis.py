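"""Sequence identity matrices and conserved-motif (fingerprint) analysis.

Percent identity between two receptor sequences is computed the way
pairwise blastp reports it: Smith–Waterman local alignment under
BLOSUM62 with gap open 11 / extend 1, identity = identical columns over
the alignment length (gap columns included), rounded to the nearest
integer percent.

Fingerprints are short ungapped motifs shared across a receptor family.
Given aligned equal-length segments, each column is classed as
``universal`` (one residue type in every member), ``subset:<group>``
(uniform within one labelled group only) or ``variable``; conserved
blocks can also be scanned out of a multiple sequence alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "ProteinSeq",
    "IdentityMatrix",
    "MotifBlock",
    "AlignParams",
    "read_fasta",
    "pairwise_identity",
    "identity_matrix",
    "column_conservation",
    "find_conserved_blocks",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinSeq:
    """An ungapped, uppercase amino-acid sequence with an identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues) - _AA
        if bad:
            raise ValueError(f"non-standard residues in {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[ProteinSeq]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(ProteinSeq(id=rec.id, residues=str(rec.seq).upper()))
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out


@dataclass(frozen=True)
class AlignParams:
    """blastp-default local alignment parameters."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


def _aligner(params: AlignParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # Biopython scores an L-residue gap as open + L*extend with these settings.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def pairwise_identity(
    a: ProteinSeq, b: ProteinSeq, params: AlignParams = AlignParams()
) -> int:
    """Percent identity of the optimal local alignment, nearest integer."""
    if not a.residues or not b.residues:
        raise ValueError("empty sequence")
    # canonical argument order: co-optimal alignments can differ in their
    # identity count, so tie-breaking must not depend on input order
    if b.residues < a.residues:
        a, b = b, a
    alignment = _aligner(params).align(a.residues, b.residues)[0]
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return round(100.0 * counts.identities / length)


@dataclass(frozen=True)
class IdentityMatrix:
    labels: tuple[str, ...]
    values: tuple[tuple[int, ...], ...]  # integer percents, symmetric

    def __getitem__(self, pair: tuple[str, str]) -> int:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.values[i][j]

    def to_tsv(self) -> str:
        lines = ["\t".join(("",) + self.labels)]
        for lab, row in zip(self.labels, self.values):
            lines.append("\t".join([lab] + [str(v) for v in row]))
        return "\n".join(lines) + "\n"


def identity_matrix(
    seqs: Sequence[ProteinSeq], params: AlignParams = AlignParams()
) -> IdentityMatrix:
    """All-pairs identity; computed once per unordered pair, diagonal 100."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [s.id for s in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    n = len(seqs)
    vals = [[100] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            vals[i][j] = vals[j][i] = pairwise_identity(seqs[i], seqs[j], params)
    return IdentityMatrix(tuple(labels), tuple(tuple(r) for r in vals))


@dataclass(frozen=True)
class MotifBlock:
    """Equal-length aligned segments forming one fingerprint motif."""

    name: str
    members: tuple[tuple[str, str], ...]  # (label, segment)
    column_classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lengths = {len(seg) for _, seg in self.members}
        if len(lengths) > 1:
            raise ValueError(f"segment length mismatch in {self.name!r}: {lengths}")

    @property
    def length(self) -> int:
        return len(self.members[0][1])

    def universal_columns(self) -> dict[int, str]:
        """1-based positions of universal columns -> conserved residue."""
        return {
            i + 1: self.members[0][1][i]
            for i, cls in enumerate(self.column_classes)
            if cls == "universal"
        }


def load_family_fingerprints() -> tuple[dict[str, MotifBlock], dict[str, str]]:
    """Packaged TAAR-family fingerprint segments and member group labels.

    Returns ``(blocks, groups)`` where ``blocks`` maps fingerprint name to
    its :class:`MotifBlock` and ``groups`` maps member label to its
    species group (human / mouse / fish).
    """
    from importlib import resources

    text = resources.files("taarsite.data").joinpath("fingerprints.tsv").read_text()
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    header = lines[0].split("\t")
    names = header[2:]
    members: dict[str, list[tuple[str, str]]] = {n: [] for n in names}
    groups: dict[str, str] = {}
    for line in lines[1:]:
        fields = line.split("\t")
        groups[fields[0]] = fields[1]
        for n, seg in zip(names, fields[2:]):
            members[n].append((fields[0], seg))
    blocks = {n: MotifBlock(name=n, members=tuple(m)) for n, m in members.items()}
    return blocks, groups


def column_conservation(
    block: MotifBlock, groups: Mapping[str, str] | None = None
) -> MotifBlock:
    """Fill per-column conservation classes.

    A column is ``universal`` when a single residue type occurs in every
    member; otherwise ``subset:<g>`` when it is uniform within some
    labelled group ``g`` (but not across all members); else ``variable``.
    """
    groups = groups or {}
    classes = []
    for i in range(block.length):
        column = [seg[i] for _, seg in block.members]
        if len(set(column)) == 1:
            classes.append("universal")
            continue
        tag = "variable"
        for g in sorted(set(groups.values())):
            rows = [
                seg[i] for lab, seg in block.members if groups.get(lab) == g
            ]
            if len(rows) >= 2 and len(set(rows)) == 1:
                tag = f"subset:{g}"
                break
        classes.append(tag)
    return replace(block, column_classes=tuple(classes))


def find_conserved_blocks(
    msa: Sequence[tuple[str, str]],
    window: int = 11,
    min_universal: int = 4,
) -> list[MotifBlock]:
    """Scan an MSA for fingerprint-like conserved gap-free blocks.

    Maximal runs of gap-free columns of length >= ``window`` containing
    >= ``min_universal`` universal columns are reported N- to C-terminal.
    Input rows are (label, aligned sequence) of equal length; ``-`` is
    the gap character.
    """
    if not msa:
        raise ValueError("empty alignment")
    lengths = {len(s) for _, s in msa}
    if len(lengths) != 1:
        raise ValueError("unaligned input: sequences differ in length")
    (L,) = lengths
    gap_free = [all(s[i] != "-" for _, s in msa) for i in range(L)]
    universal = [
        gap_free[i] and len({s[i] for _, s in msa}) == 1 for i in range(L)
    ]
    blocks: list[MotifBlock] = []
    i = 0
    while i < L:
        if not gap_free[i]:
            i += 1
            continue
        j = i
        while j < L and gap_free[j]:
            j += 1
        run_len = j - i
        n_universal = sum(universal[i:j])
        if run_len >= window and n_universal >= min_universal:
            block = MotifBlock(
                name=f"block_{len(blocks) + 1}@{i + 1}",
                members=tuple((lab, s[i:j]) for lab, s in msa),
            )
            blocks.append(column_conservation(block))
        i = j
    return blocks
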