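"""tRNA reference model: genes, variable loops, the m7G motif, and decoding.

The m7G modification installed by METTL1/WDR4 sits in the tRNA variable loop
(canonical position 46) inside a degenerate ``ABGWY`` sequence context.  This
module parses gtRNAdb-style tRNA references, locates the variable loop (from a
dot-bracket secondary structure when available, else a positional heuristic),
scans the degenerate motif, and maps anticodons to the codons they decode under
configurable wobble rules.  Everything downstream — site calling, expression
classes, codon counting — keys off these objects.

Coordinates are 0-based half-open throughout; sequences are normalised to the
DNA alphabet (U -> T) on ingest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    FormatError,
    InputError,
    PatternError,
    StructureError,
)

DNA = set("ACGT")

COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Degenerate nucleotide codes used in motif patterns.
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise InputError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TRNAGene:
    """One tRNA gene.

    ``sequence`` is the mature, genomically encoded tRNA in DNA alphabet
    (T in place of U).  ``variable_loop`` is a 0-based half-open interval into
    ``sequence``.  ``isotype_key`` aggregates isodecoders sharing an amino acid
    and anticodon; ``isodecoder_id`` identifies the individual gene.
    """

    id: str
    amino_acid: str
    anticodon: str
    sequence: str
    variable_loop: Interval | None = None
    isodecoder_id: str = ""
    flag: str | None = None  # set when the header could not be parsed

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not set(self.sequence) <= DNA:
            bad = sorted(set(self.sequence) - DNA)
            raise FormatError(f"{self.id}: non-DNA characters {bad} in sequence")
        if self.flag is None:
            if len(self.anticodon) != 3 or not set(self.anticodon) <= DNA:
                raise FormatError(f"{self.id}: invalid anticodon {self.anticodon!r}")
        if self.variable_loop is not None:
            vl = self.variable_loop
            if not (0 <= vl.start < vl.end <= len(self.sequence)):
                raise InputError(f"{self.id}: variable loop {vl} out of bounds")
        if not self.isodecoder_id:
            self.isodecoder_id = self.id

    @property
    def isotype_key(self) -> str:
        """Amino acid + anticodon, the isotype aggregation key (e.g. Val-AAC)."""
        return f"{self.amino_acid}-{self.anticodon}"


@dataclass(frozen=True)
class MotifPattern:
    """Degenerate motif marking the m7G site; the modified G is anchored.

    The default ``ABGWY`` places the methylated guanosine at offset 2.
    """

    iupac: str = "ABGWY"
    modified_offset: int = 2

    def __post_init__(self) -> None:
        for ch in self.iupac:
            if ch not in IUPAC:
                raise PatternError(f"invalid degenerate-code character {ch!r}")
        if not (0 <= self.modified_offset < len(self.iupac)):
            raise PatternError("modified_offset outside the pattern")
        if "G" not in IUPAC[self.iupac[self.modified_offset]]:
            raise PatternError("character at modified_offset cannot match G")

    def literal_expansions(self) -> list[str]:
        """All literal strings matching the pattern (oracle-sized for ABGWY: 12)."""
        out = [""]
        for ch in self.iupac:
            out = [p + b for p in out for b in sorted(IUPAC[ch])]
        return out


# Wobble tables: anticodon position-34 base -> allowed codon third-position bases.
# Watson-Crick pairing contributes the reverse complement; the wobble modes widen
# the third-position set per the classic wobble rules, optionally treating A34 as
# inosine (the usual state of eukaryotic A34 tRNAs), which reads U/C/A.
_STRICT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE_EXTRA = {"G": "T", "T": "G", "C": "", "A": ""}
_INOSINE_EXTRA = {"A": "CA"}

DECODING_MODES = ("strict_wc", "crick_wobble", "crick_wobble_inosine")


@dataclass(frozen=True)
class DecodingPolicy:
    """Which codons an anticodon reads, as a function of its position-34 base."""

    mode: str = "crick_wobble_inosine"

    def __post_init__(self) -> None:
        if self.mode not in DECODING_MODES:
            raise InputError(f"unknown decoding mode {self.mode!r}")

    @property
    def table(self) -> dict[str, frozenset[str]]:
        """Map anticodon position-34 base -> allowed codon third-position bases."""
        tab = {}
        for b34 in "ACGT":
            allowed = _STRICT[b34]
            if self.mode in ("crick_wobble", "crick_wobble_inosine"):
                allowed += _WOBBLE_EXTRA[b34]
            if self.mode == "crick_wobble_inosine":
                allowed += _INOSINE_EXTRA.get(b34, "")
            tab[b34] = frozenset(allowed)
        return tab


_HEADER_RE = re.compile(
    r"tRNA-(?P<aa>[A-Za-z]{3}|iMet|fMet|SeC|Sup|Und)-(?P<ac>[ACGTUacgtu]{3})"
)


def parse_gtrnadb_header(header: str) -> tuple[str, str] | None:
    """Extract (amino_acid, anticodon) from a gtRNAdb-style FASTA id.

    ``Homo_sapiens_tRNA-Val-AAC-1-1`` -> ``("Val", "AAC")``.  Returns None when
    the grammar does not match.
    """
    m = _HEADER_RE.search(header)
    if m is None:
        return None
    return m.group("aa"), m.group("ac").upper().replace("U", "T")


def load_trna_reference(
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
    fallback_window: tuple[int, int] = (-27, -12),
    cca_appended: bool = False,
) -> list[TRNAGene]:
    """Load tRNA genes from FASTA, locating variable loops for each record.

    ``annotation_path``, if given, is a FASTA-like file whose per-record lines
    are dot-bracket strings of the same length as the sequence; when present,
    loops are located structurally, otherwise via the fallback window (an
    offset pair relative to the 3' end).  Records whose headers do not follow
    the gtRNAdb grammar are returned with ``flag`` set, never dropped.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise EmptyInputError(f"{fasta_path}: no FASTA records")

    structures: dict[str, str] = {}
    if annotation_path is not None:
        structures = _read_structure_file(annotation_path)

    genes: list[TRNAGene] = []
    for rec in records:
        parsed = parse_gtrnadb_header(rec.id) or parse_gtrnadb_header(
            rec.description
        )
        seq = str(rec.seq)
        if parsed is None:
            gene = TRNAGene(
                id=rec.id,
                amino_acid="",
                anticodon="",
                sequence=seq,
                flag="unparseable isotype",
            )
            genes.append(gene)
            continue
        aa, ac = parsed
        gene = TRNAGene(id=rec.id, amino_acid=aa, anticodon=ac, sequence=seq)
        db = structures.get(rec.id)
        if db is not None and len(db) != len(gene.sequence):
            raise FormatError(
                f"{rec.id}: structure length {len(db)} != sequence length "
                f"{len(gene.sequence)}"
            )
        gene.variable_loop = locate_variable_loop(
            gene, dot_bracket=db, fallback_window=fallback_window,
            cca_appended=cca_appended,
        )
        genes.append(gene)
    return genes


def _read_structure_file(path: str | Path) -> dict[str, str]:
    """Read a FASTA-like file whose body lines are dot-bracket strings."""
    structures: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    structures[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        structures[name] = "".join(chunks)
    return structures


def _pair_map(dot_bracket: str) -> list[int]:
    """Pairing partner per position (-1 if unpaired); raises on imbalance."""
    pairs = [-1] * len(dot_bracket)
    stack: list[int] = []
    for i, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif ch not in ".,:_-":
            raise StructureError(f"invalid structure character {ch!r}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def locate_variable_loop(
    gene: TRNAGene,
    dot_bracket: str | None = None,
    fallback_window: tuple[int, int] = (-27, -12),
    cca_appended: bool = False,
) -> Interval:
    """Locate the variable loop of a tRNA.

    With a secondary structure, the loop is the unpaired run strictly between
    the 3' side of the anticodon stem and the 5' side of the T-stem: we find
    the hairpin loop containing the anticodon, walk to the 3'-most position of
    the helix closing it, and extend through unpaired positions until the next
    paired base.  Without structure, a positional heuristic window relative to
    the 3' end is used (default [len-27, len-12), which covers canonical
    positions 44-48 on a 76-nt tRNA); a trailing CCA is excluded from the
    length when ``cca_appended`` is set.
    """
    seq = gene.sequence
    if dot_bracket is not None:
        if len(dot_bracket) != len(seq):
            raise FormatError(
                f"{gene.id}: structure length {len(dot_bracket)} != "
                f"sequence length {len(seq)}"
            )
        pairs = _pair_map(dot_bracket)
        loop = _anticodon_hairpin(gene, pairs)
        if loop is None:
            raise StructureError(
                f"{gene.id}: no hairpin loop containing the anticodon"
            )
        # 3'-most base of the helix closing the anticodon hairpin.
        stem_3p = pairs[loop.start - 1]
        while stem_3p + 1 < len(seq) and pairs[stem_3p + 1] != -1 \
                and pairs[stem_3p + 1] < loop.start:
            stem_3p += 1
        start = stem_3p + 1
        end = start
        while end < len(seq) and pairs[end] == -1:
            end += 1
        if start >= end:
            raise StructureError(f"{gene.id}: empty variable loop")
        return Interval(start, end)

    eff_len = len(seq) - (3 if cca_appended and seq.endswith("CCA") else 0)
    start = eff_len + fallback_window[0]
    end = eff_len + fallback_window[1]
    if start < 0 or end > len(seq) or start >= end:
        raise DegenerateInputError(
            f"{gene.id}: fallback window [{start}, {end}) out of range for "
            f"length-{len(seq)} sequence"
        )
    return Interval(start, end)


def _anticodon_hairpin(gene: TRNAGene, pairs: list[int]) -> Interval | None:
    """The hairpin loop (maximal unpaired run closed by a pair) holding the
    anticodon; falls back to the second hairpin when the anticodon sequence is
    not found in any loop."""
    runs: list[Interval] = []
    i = 0
    n = len(pairs)
    while i < n:
        if pairs[i] == -1:
            j = i
            while j < n and pairs[j] == -1:
                j += 1
            # hairpin iff the flanking bases pair with each other
            if i > 0 and j < n and pairs[i - 1] == j:
                runs.append(Interval(i, j))
            i = j
        else:
            i += 1
    if not runs:
        return None
    for run in runs:
        if gene.anticodon and gene.anticodon in gene.sequence[run.start:run.end]:
            return run
    return runs[1] if len(runs) > 1 else runs[0]


def scan_motif(
    sequence: str,
    window: Interval,
    pattern: MotifPattern = MotifPattern(),
    allow_overhang: bool = True,
) -> list[int]:
    """Scan a degenerate motif inside ``window``; return modified-G positions.

    A match must start inside the window.  With ``allow_overhang`` (default)
    the match may extend past the window end as long as the modified G itself
    lies inside the window; otherwise the entire match must fit in the window.
    Overlapping matches are all reported, in ascending order.
    """
    sequence = sequence.upper().replace("U", "T")
    if window.start < 0 or window.end > len(sequence):
        raise InputError(f"window {window} outside sequence bounds")
    sets = [IUPAC[ch] for ch in pattern.iupac]
    k = len(sets)
    hits: list[int] = []
    for s in range(window.start, window.end):
        if s + k > len(sequence):
            break
        if not allow_overhang and s + k > window.end:
            break
        g_pos = s + pattern.modified_offset
        if allow_overhang and g_pos >= window.end:
            break
        if all(sequence[s + i] in sets[i] for i in range(k)):
            hits.append(g_pos)
    return hits


def decoded_codons(anticodon: str, policy: DecodingPolicy = DecodingPolicy()) -> set[str]:
    """Codons read by an anticodon (5'->3') under the given wobble policy.

    Codon positions 1-2 Watson-Crick match anticodon positions 36-35; the
    codon third-position set depends on the anticodon position-34 base (the
    anticodon's first base, 5'->3') per the policy table.
    """
    anticodon = anticodon.upper().replace("U", "T")
    if len(anticodon) != 3 or not set(anticodon) <= DNA:
        raise InputError(f"invalid anticodon {anticodon!r}")
    first_two = revcomp(anticodon)[:2]
    third = policy.table[anticodon[0]]
    return {first_two + b for b in third}


def m7g_codon_set(
    m7g_trnas: Iterable[TRNAGene], policy: DecodingPolicy = DecodingPolicy()
) -> set[str]:
    """Union of decoded codons over the distinct anticodons of m7G tRNAs."""
    anticodons = {g.anticodon for g in m7g_trnas}
    if not anticodons:
        raise EmptyInputError("no m7G tRNAs supplied")
    out: set[str] = set()
    for ac in anticodons:
        out |= decoded_codons(ac, policy)
    return out


def decoding_table_rows(
    genes: Sequence[TRNAGene], policy: DecodingPolicy
) -> list[tuple[str, str, str]]:
    """(anticodon, policy mode, comma-joined codons) rows for a TSV dump."""
    rows = []
    for ac in sorted({g.anticodon for g in genes if g.anticodon}):
        codons = ",".join(sorted(decoded_codons(ac, policy)))
        rows.append((ac, policy.mode, codons))
    return rows
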