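"""Reference amplicons and in-silico bisulfite chemistry.

Bisulfite (BS) treatment deaminates unmethylated cytosine to uracil (read
as thymine after PCR) while 5-methylcytosine is protected.  Because the
two strands of BS-treated DNA are no longer complementary, each PCR primer
pair amplifies exactly one strand, and methylation is read strand by
strand.  This module models the chemistry on a reference amplicon:

* strand handling (a bottom-strand assay is represented by
  reverse-complementing the genomic sequence once, at load time; all
  downstream logic is then strand-agnostic),
* CpG site discovery on the assayed strand,
* stochastic in-silico conversion of a clone with a known methylation
  state, and
* validation that a primer pair is BS-specific and methylation-unbiased.

Coordinates are 0-based half-open on the assayed strand throughout; the
reporting layer translates to the 1-based CpG ordinals (5'->3' on the
assayed strand) used in lollipop figures.
"""

from __future__ import annotations


import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceError",
    "PrimerPair",
    "ConversionModel",
    "Amplicon",
    "discover_cpg_sites",
    "reverse_complement",
    "in_silico_convert",
    "validate_primer_pair",
    "PrimerValidationReport",
    "read_reference_fasta",
    "write_cpg_bed",
]

_VALID = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CPG_RE = re.compile("CG")

TOP = "top"
BOTTOM = "bottom"
STRANDS = (TOP, BOTTOM)


class SequenceError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


def _check_sequence(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    for i, base in enumerate(seq):
        if base not in _VALID:
            raise SequenceError(
                f"{what} contains non-nucleotide character {base!r} at position {i}"
            )
    return seq


def discover_cpg_sites(ref_seq: str) -> list[int]:
    """Return 0-based positions of the C of every CpG dinucleotide.

    ``N`` never participates in a CpG.  Raises :class:`SequenceError` for
    characters outside {A, C, G, T, N}.
    """
    seq = _check_sequence(ref_seq, "ref_seq")
    return [m.start() for m in _CPG_RE.finditer(seq)]


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    seq = _check_sequence(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A strand-specific primer pair for BS-converted DNA.

    The forward primer matches the 5' end of the BS-converted target
    strand; the reverse primer anneals to (is the reverse complement of)
    the 3' end of that same converted strand.
    """

    forward_seq: str
    reverse_seq: str
    target_strand: str = TOP

    def __post_init__(self) -> None:
        if not self.forward_seq or not self.reverse_seq:
            raise ValueError("primer sequences must be non-empty")
        object.__setattr__(self, "forward_seq", _check_sequence(self.forward_seq, "forward primer"))
        object.__setattr__(self, "reverse_seq", _check_sequence(self.reverse_seq, "reverse primer"))
        if self.target_strand not in STRANDS:
            raise ValueError(f"target_strand must be one of {STRANDS}")


@dataclass(frozen=True)
class ConversionModel:
    """Stochastic model of bisulfite conversion chemistry.

    Parameters
    ----------
    conversion_rate
        Probability that an unmethylated C is deaminated and reads as T.
        Commercial kits specify >= 0.995.
    protection_rate
        Probability that a methylated C survives treatment and reads as C
        (1 - protection_rate is the inappropriate-conversion rate).
    """

    conversion_rate: float = 0.995
    protection_rate: float = 0.995

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "protection_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


PERFECT_CONVERSION = ConversionModel(1.0, 1.0)


@dataclass(frozen=True)
class Amplicon:
    """A reference amplicon written 5'->3' on the assayed strand.

    ``ref_seq`` is the *untreated* genomic sequence of the strand the
    primer pair amplifies.  ``assayed_strand`` records which genomic
    strand that is; ``gene_strand_label`` is annotation only (e.g. FOXP3
    is encoded on the genomic bottom strand, so its coding strand is
    ``bottom``).  ``cpg_positions`` are the 0-based positions of the C of
    each CpG in the assayed strand's 5'->3' frame; CpG ordinals used in
    reports are 1-based in this order.
    """

    name: str
    ref_seq: str
    assayed_strand: str = TOP
    gene_strand_label: str | None = None
    cpg_positions: tuple[int, ...] = field(default=None)  # type: ignore[assignment]
    primers: PrimerPair | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_seq", _check_sequence(self.ref_seq, f"amplicon {self.name}"))
        if self.assayed_strand not in STRANDS:
            raise ValueError(f"assayed_strand must be one of {STRANDS}")
        if self.cpg_positions is None:
            object.__setattr__(self, "cpg_positions", tuple(discover_cpg_sites(self.ref_seq)))
        else:
            pos = tuple(self.cpg_positions)
            if list(pos) != sorted(set(pos)):
                raise ValueError("cpg_positions must be strictly increasing")
            for p in pos:
                if not (0 <= p < len(self.ref_seq) - 1 and self.ref_seq[p] == "C" and self.ref_seq[p + 1] == "G"):
                    raise ValueError(
                        f"position {p} is not the C of a CpG on the assayed strand of {self.name}"
                    )
            object.__setattr__(self, "cpg_positions", pos)

    @classmethod
    def from_genomic(
        cls,
        name: str,
        genomic_top_seq: str,
        assayed_strand: str = TOP,
        gene_strand_label: str | None = None,
        primers: PrimerPair | None = None,
    ) -> "Amplicon":
        """Build an amplicon from the genomic top-strand sequence.

        A bottom-strand assay reverse-complements the sequence here, once;
        everything downstream works in the assayed strand's frame.
        """
        seq = _check_sequence(genomic_top_seq, f"amplicon {name}")
        if assayed_strand == BOTTOM:
            seq = reverse_complement(seq)
        return cls(name=name, ref_seq=seq, assayed_strand=assayed_strand,
                   gene_strand_label=gene_strand_label, primers=primers)

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    @property
    def cpg_index(self) -> dict[int, int]:
        """Map ref position of a CpG C -> 0-based CpG index."""
        return {p: i for i, p in enumerate(self.cpg_positions)}

    def non_cpg_c_positions(self) -> list[int]:
        """Positions of cytosines outside CpG context (conversion-QC sites)."""
        cpg = set(self.cpg_positions)
        return [i for i, b in enumerate(self.ref_seq) if b == "C" and i not in cpg]

    def converted_reference(self, methylated_cpgs: bool = False) -> str:
        """Deterministic fully-converted reference sequence.

        With ``methylated_cpgs=False`` every C reads T (the
        all-unmethylated template used for primer design and alignment);
        with ``True`` CpG Cs are kept as C.
        """
        out = list(self.ref_seq.replace("C", "T"))
        if methylated_cpgs:
            for p in self.cpg_positions:
                out[p] = "C"
        return "".join(out)


def in_silico_convert(
    amplicon: Amplicon,
    clone_methylation_state: Sequence[bool] | np.ndarray,
    model: ConversionModel = PERFECT_CONVERSION,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Bisulfite-convert one clone of the amplicon in silico.

    ``clone_methylation_state`` holds one boolean per CpG site (True =
    methylated).  Unmethylated Cs (all non-CpG Cs, plus CpG Cs with state
    False) read T with probability ``model.conversion_rate``; methylated
    CpG Cs read C with probability ``model.protection_rate``.  A, G, T
    and N are never altered.  Deterministic given the generator state.
    """
    state = np.asarray(clone_methylation_state, dtype=bool)
    if state.shape != (amplicon.n_cpg,):
        raise ValueError(
            f"methylation state has length {state.size}, amplicon "
            f"{amplicon.name} has {amplicon.n_cpg} CpG sites"
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = list(amplicon.ref_seq)
    cpg_index = amplicon.cpg_index
    for i, base in enumerate(amplicon.ref_seq):
        if base != "C":
            continue
        j = cpg_index.get(i)
        if j is not None and state[j]:
            if rng.random() >= model.protection_rate:
                out[i] = "T"
        else:
            if rng.random() < model.conversion_rate:
                out[i] = "T"
    return "".join(out)


@dataclass
class PrimerValidationReport:
    ok: bool
    violations: list[str]
    forward_span: tuple[int, int] | None = None
    reverse_span: tuple[int, int] | None = None


def _best_hamming_placement(primer: str, template: str) -> tuple[int, int]:
    """Slide ``primer`` over ``template``; return (start, mismatches) of best fit."""
    n, m = len(template), len(primer)
    if m > n:
        return 0, m
    best = (0, m + 1)
    for s in range(n - m + 1):
        mm = sum(1 for a, b in zip(primer, template[s:s + m]) if a != b)
        if mm < best[1]:
            best = (s, mm)
            if mm == 0:
                break
    return best


def validate_primer_pair(
    primers: PrimerPair,
    amplicon: Amplicon,
    min_mismatches_vs_genomic: int = 2,
    max_localization_mismatch_frac: float = 0.2,
) -> PrimerValidationReport:
    """Check that a primer pair is BS-specific and methylation-unbiased.

    The pair is localized on the fully-converted all-unmethylated
    template (the sequence a completely converted, unmethylated molecule
    presents).  Three classes of violation are flagged:

    a. a primer footprint overlaps the C of a CpG — amplification would
       depend on that site's methylation state;
    b. a primer retains C at a position where the converted template
       reads T — the primer would favour unconverted DNA;
    c. fewer than ``min_mismatches_vs_genomic`` mismatches against the
       untreated genomic sequence — the primer could amplify
       non-BS-treated DNA.
    """
    converted = amplicon.converted_reference(methylated_cpgs=False)
    genomic = amplicon.ref_seq
    violations: list[str] = []

    def locate(primer: str, label: str) -> tuple[int, int] | None:
        start, mm = _best_hamming_placement(primer, converted)
        if mm > max_localization_mismatch_frac * len(primer):
            raise ValueError(
                f"{label} primer cannot be localized on the converted "
                f"{amplicon.assayed_strand}-strand template of {amplicon.name} "
                f"(best placement has {mm} mismatches)"
            )
        return start, start + len(primer)

    fwd_span = locate(primers.forward_seq, "forward")
    rev_rc = reverse_complement(primers.reverse_seq)
    rev_span = locate(rev_rc, "reverse")

    for label, span, primer_on_template in (
        ("forward", fwd_span, primers.forward_seq),
        ("reverse", rev_span, rev_rc),
    ):
        s, e = span
        cpg_hits = [p for p in amplicon.cpg_positions if s <= p < e]
        if cpg_hits:
            violations.append(
                f"(a) {label} primer footprint overlaps CpG C at position(s) {cpg_hits}"
            )
        retained = [
            s + k
            for k, b in enumerate(primer_on_template)
            if b == "C" and genomic[s + k] == "C" and converted[s + k] == "T"
        ]
        if retained:
            violations.append(
                f"(b) {label} primer retains C at converted-T position(s) {retained}"
            )
        mm_genomic = sum(
            1 for k, b in enumerate(primer_on_template) if b != genomic[s + k]
        )
        if mm_genomic < min_mismatches_vs_genomic:
            violations.append(
                f"(c) {label} primer has only {mm_genomic} mismatch(es) vs the "
                f"untreated genomic sequence (< {min_mismatches_vs_genomic})"
            )

    return PrimerValidationReport(
        ok=not violations,
        violations=violations,
        forward_span=fwd_span,
        reverse_span=rev_span,
    )


def read_reference_fasta(path: str | Path) -> dict[str, Amplicon]:
    """Read reference amplicons from FASTA.

    Headers carry the region name and assayed strand as
    ``name|strand=top`` (strand defaults to top).  Sequences are the
    untreated genomic top-strand sequence; bottom-strand records are
    reverse-complemented at load.
    """
    amplicons: dict[str, Amplicon] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        strand = TOP
        if "|" in name:
            name, _, rest = name.partition("|")
            for token in rest.split("|"):
                key, _, value = token.partition("=")
                if key == "strand":
                    strand = value
        amp = Amplicon.from_genomic(name, str(record.seq), assayed_strand=strand)
        amplicons[f"{name}|{strand}"] = amp
    return amplicons


def write_reference_fasta(amplicons: Iterable[Amplicon], path: str | Path) -> None:
    """Write amplicons as FASTA with ``name|strand=`` headers.

    Sequences are written as genomic top-strand so the file round-trips
    through :func:`read_reference_fasta`.
    """
    records = []
    for amp in amplicons:
        seq = amp.ref_seq if amp.assayed_strand == TOP else reverse_complement(amp.ref_seq)
        records.append(
            SeqRecord(Seq(seq), id=f"{amp.name}|strand={amp.assayed_strand}", description="")
        )
    SeqIO.write(records, str(path), "fasta")


def write_cpg_bed(amplicon: Amplicon, path: str | Path) -> None:
    """Export CpG sites as BED (0-based half-open, strand column)."""
    strand_symbol = "+" if amplicon.assayed_strand == TOP else "-"
    with open(path, "w") as fh:
        for ordinal, p in enumerate(amplicon.cpg_positions, start=1):
            fh.write(
                f"{amplicon.name}\t{p}\t{p + 2}\tCpG_{ordinal}\t0\t{strand_symbol}\n"
            )
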