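"""In-silico DNA cassette construction and Type IIS assembly checks.

The ribosome-display cassette is laid out as

    T7 promoter -> RBS -> nanobody ORF -> SLEHHHHHH linker -> tolA-type
    stall spacer -> terminal restriction cassette

and must stay stop-free from the start codon through the spacer so the
ribosome stalls at the 3' end instead of releasing.  This module reverse
translates the protein design into that cassette, scans for Type IIS
recognition sites (BsaI, BbsI, BspQI), simulates sticky-end digestion and
ligation of fragment sets, and verifies an assembled cassette.

The RBS and the stall spacer are synthetic placeholders of realistic length
(the authentic vector sequences are not reproduced here); the spacer embeds
the reverse complement of the reverse-transcription primer
``CTTCAGTTGCCGCTTTCTTTCTTG`` so RT/NGS simulation stays consistent, and the
terminal element carries the reverse complement of the TolA-R2 primer with
its minus-strand BspQI site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .design import AMINO_ACIDS, LibraryDesign

# ---------------------------------------------------------------------------
# constants & small helpers
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(dna: str) -> str:
    return dna.translate(_RC)[::-1]


def translate(dna: str) -> str:
    """Standard-code translation (no stop trimming; '*' marks stops)."""
    return str(Seq(dna).translate())


#: One preferred codon per amino acid (common E. coli usage).
ECOLI_PREFERRED_CODONS = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}

T7_PROMOTER_CORE = "TAATACGACTCACTATAG"
#: 5' flank carrying the T7 promoter core (the 5'-Flank-F primer region).
PROMOTER_SEQ = "CGAAATTAATACGACTCACTATAGGGAGAC"
#: Synthetic placeholder ribosome-binding-site region (Shine-Dalgarno AGGAGG
#: context ending just before the start codon); not the authentic vector RBS.
RBS_SEQ = "TTAACTTTAAGAAGGAGATATACAT"
LINKER_PEPTIDE = "SLEHHHHHH"
#: Reverse-transcription primer used to recover selected mRNA.
RT_PRIMER = "CTTCAGTTGCCGCTTTCTTTCTTG"
#: Synthetic truncated tolA-like stall spacer peptide (placeholder).
SPACER_PEPTIDE_PREFIX = "GKAEAAKAKAEAAKGDDAKAAE"
TOLA_R2_PRIMER = "CAGCAGCTATAGCTCTTCAAAACC"

STOP_CODONS = {"TAA", "TAG", "TGA"}


class AssemblyError(ValueError):
    """Raised for incompatible/ambiguous fragment joins or bad inputs."""


@dataclass(frozen=True)
class TypeIIS:
    """A Type IIS enzyme: cuts downstream of its recognition site.

    ``spacer`` is the gap between the recognition sequence and the top-strand
    cut; ``overhang`` the length of the 5' overhang left behind.
    """

    name: str
    site: str
    spacer: int
    overhang: int


#: Built-in enzyme set (standard definitions; BspQI is a SapI isoschizomer).
ENZYMES = {
    "BsaI": TypeIIS("BsaI", "GGTCTC", 1, 4),
    "BbsI": TypeIIS("BbsI", "GAAGAC", 2, 4),
    "BspQI": TypeIIS("BspQI", "GCTCTTC", 1, 3),
}


# ---------------------------------------------------------------------------
# codon table / reverse translation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonTable:
    """One assigned codon per standard amino acid."""

    codon_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = [aa for aa in AMINO_ACIDS if aa not in self.codon_of]
        if missing:
            raise AssemblyError(f"codon table missing amino acids: {missing}")
        for aa, codon in self.codon_of.items():
            if translate(codon) != aa:
                raise AssemblyError(
                    f"codon {codon} assigned to {aa} translates to {translate(codon)}"
                )

    @classmethod
    def ecoli(cls) -> "CodonTable":
        return cls(dict(ECOLI_PREFERRED_CODONS))

    def encode(self, protein: str) -> str:
        try:
            return "".join(self.codon_of[aa] for aa in protein)
        except KeyError as exc:
            raise AssemblyError(f"no codon assigned for amino acid {exc}") from exc


@dataclass(frozen=True)
class OrfElement:
    """Reverse-translated ORF DNA with randomized codon slots.

    ``slots`` maps a 0-based protein position to its alternative codons
    (one per allowed amino acid); ``sequence`` carries the consensus codon
    at each slot.
    """

    sequence: str
    slots: dict[int, dict[str, str]] = field(default_factory=dict)

    def codon_offset(self, position: int) -> int:
        return 3 * position


def reverse_translate(protein: str, table: CodonTable,
                      design: LibraryDesign | None = None) -> OrfElement:
    """Encode a protein as DNA, marking design-randomized positions as slots.

    Fixed positions use the table's preferred codon.  When a design is given,
    the protein must be consistent with it (each randomized position holds an
    allowed letter, fixed positions the scaffold letter) and every allowed
    amino acid at a randomized position gets a slot codon.
    """
    slots: dict[int, dict[str, str]] = {}
    if design is not None:
        if len(protein) != len(design.scaffold):
            raise AssemblyError(
                f"protein length {len(protein)} != scaffold length "
                f"{len(design.scaffold)}"
            )
        randomized = set(design.randomized_positions)
        for i, aa in enumerate(protein):
            if i in randomized:
                comp = design.composition_at(i)
                if aa not in comp.weights:
                    raise AssemblyError(
                        f"position {i}: {aa} not in the design's allowed set"
                    )
                slots[i] = {a: table.codon_of[a] for a in comp.letters}
            elif aa != design.scaffold[i]:
                raise AssemblyError(
                    f"position {i}: fixed residue {aa} differs from scaffold "
                    f"{design.scaffold[i]}"
                )
    return OrfElement(sequence=table.encode(protein), slots=slots)


# ---------------------------------------------------------------------------
# restriction-site scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RestrictionSiteHit:
    enzyme: str
    recognition: str
    start: int      # plus-strand coordinate of the matched substring
    strand: str     # '+' or '-'


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def scan_restriction_sites(dna: str,
                           enzymes: list[str] | dict[str, str] | None = None
                           ) -> list[RestrictionSiteHit]:
    """All recognition-site occurrences on both strands.

    Minus-strand hits are reported at the plus-strand coordinate of the
    reverse-complement match.  ``enzymes`` may be names from the built-in
    set, or a mapping name -> recognition sequence.
    """
    bad = set(dna) - set("ACGT")
    if bad:
        raise AssemblyError(f"non-ACGT characters in sequence: {sorted(bad)}")
    if enzymes is None:
        table = {name: e.site for name, e in ENZYMES.items()}
    elif isinstance(enzymes, dict):
        table = dict(enzymes)
    else:
        table = {}
        for name in enzymes:
            if name not in ENZYMES:
                raise AssemblyError(
                    f"unknown enzyme {name!r}; built-ins: {sorted(ENZYMES)}"
                )
            table[name] = ENZYMES[name].site
    hits: list[RestrictionSiteHit] = []
    for name, site in table.items():
        for i in _find_all(dna, site):
            hits.append(RestrictionSiteHit(name, site, i, "+"))
        rc_site = revcomp(site)
        for i in _find_all(dna, rc_site):
            hits.append(RestrictionSiteHit(name, site, i, "-"))
    hits.sort(key=lambda h: (h.start, h.enzyme, h.strand))
    return hits


# ---------------------------------------------------------------------------
# fragments, digestion, ligation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    """A dsDNA piece with declared 5' sticky ends after Type IIS digestion.

    ``seq`` includes the overhang bases at both ends; ``left_overhang`` /
    ``right_overhang`` are the terminal ``k`` bases (None for a blunt outer
    end).  Ligating two fragments merges the shared overhang once.
    """

    name: str
    seq: str
    left_overhang: str | None = None
    right_overhang: str | None = None

    def __post_init__(self) -> None:
        if self.left_overhang and not self.seq.startswith(self.left_overhang):
            raise AssemblyError(
                f"{self.name}: left overhang {self.left_overhang} is not a "
                "prefix of the fragment sequence"
            )
        if self.right_overhang and not self.seq.endswith(self.right_overhang):
            raise AssemblyError(
                f"{self.name}: right overhang {self.right_overhang} is not a "
                "suffix of the fragment sequence"
            )


def type_iis_digest(dna: str, enzyme: str) -> list[Fragment]:
    """Cut at every plus-strand site of a Type IIS enzyme.

    Fragments carry the 5' overhang bases at both cut ends (each overhang is
    therefore present in both flanking fragments, and re-ligation merges it
    back once).  Minus-strand sites are not cut here; scan both strands first
    if that matters for the construct.
    """
    enz = ENZYMES[enzyme]
    cuts: list[tuple[int, int]] = []   # (top cut, bottom cut) positions
    for i in _find_all(dna, enz.site):
        top = i + len(enz.site) + enz.spacer
        bottom = top + enz.overhang
        if bottom <= len(dna):
            cuts.append((top, bottom))
    cuts.sort()
    fragments: list[Fragment] = []
    prev_top, prev_ov = 0, None
    for k, (top, bottom) in enumerate(cuts):
        ov = dna[top:bottom]
        fragments.append(Fragment(
            name=f"frag{len(fragments)}",
            seq=dna[prev_top:bottom],
            left_overhang=prev_ov,
            right_overhang=ov,
        ))
        prev_top, prev_ov = top, ov
    fragments.append(Fragment(
        name=f"frag{len(fragments)}",
        seq=dna[prev_top:],
        left_overhang=prev_ov,
        right_overhang=None,
    ))
    return fragments


@dataclass(frozen=True)
class Element:
    """A named cassette segment in 0-based half-open DNA coordinates."""

    name: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ConstructTemplate:
    """An assembled cassette: full sequence plus a contiguous element map."""

    sequence: str
    elements: tuple[Element, ...]
    slots: dict[int, dict[str, str]] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        cursor = 0
        for e in self.elements:
            if e.start != cursor:
                raise AssemblyError(
                    f"element {e.name} starts at {e.start}, expected {cursor}"
                )
            cursor = e.end
        if cursor != len(self.sequence):
            raise AssemblyError("element map does not cover the sequence")

    def element(self, name: str) -> Element:
        for e in self.elements:
            if e.name == name:
                return e
        raise AssemblyError(f"no element named {name!r}")

    def has_element(self, name: str) -> bool:
        return any(e.name == name for e in self.elements)

    def segment(self, name: str) -> str:
        e = self.element(name)
        return self.sequence[e.start:e.end]


def simulate_assembly(fragments: list[Fragment]) -> ConstructTemplate:
    """Ligate fragments by unique sticky-end matching.

    The join order is dictated by the overhang graph, so the result is
    independent of input order.  Every junction must pair exactly one right
    overhang with exactly one left overhang; anything else is an assembly
    error naming the junction.  Recognition sites surviving inside the
    product are recorded as warnings (mirroring unintended-fragment
    cleanup in real builds).
    """
    if not fragments:
        raise AssemblyError("no fragments to assemble")
    starts = [f for f in fragments if f.left_overhang is None]
    if len(starts) != 1:
        raise AssemblyError(
            f"expected exactly one 5'-terminal fragment (no left overhang), "
            f"found {len(starts)}"
        )
    remaining = [f for f in fragments if f is not starts[0]]
    chain = [starts[0]]
    while remaining:
        ov = chain[-1].right_overhang
        if ov is None:
            raise AssemblyError(
                f"fragment {chain[-1].name} is 3'-terminal but "
                f"{[f.name for f in remaining]} remain unjoined"
            )
        matches = [f for f in remaining if f.left_overhang == ov]
        if len(matches) == 0:
            raise AssemblyError(
                f"no fragment carries left overhang {ov} to join after "
                f"{chain[-1].name}"
            )
        if len(matches) > 1:
            raise AssemblyError(
                f"ambiguous junction after {chain[-1].name}: overhang {ov} "
                f"matches {[f.name for f in matches]}"
            )
        chain.append(matches[0])
        remaining.remove(matches[0])
    if chain[-1].right_overhang is not None:
        raise AssemblyError(
            f"fragment {chain[-1].name} ends in overhang "
            f"{chain[-1].right_overhang} with nothing to join"
        )
    seq_parts = [chain[0].seq]
    elements = [Element(chain[0].name, 0, len(chain[0].seq))]
    for f in chain[1:]:
        k = len(f.left_overhang)
        start = elements[-1].end
        seq_parts.append(f.seq[k:])
        elements.append(Element(f.name, start, start + len(f.seq) - k))
    sequence = "".join(seq_parts)
    warnings = tuple(
        f"internal {h.enzyme} site at {h.start} ({h.strand})"
        for h in scan_restriction_sites(sequence)
    )
    return ConstructTemplate(sequence=sequence, elements=tuple(elements),
                             warnings=warnings)


# ---------------------------------------------------------------------------
# cassette construction & verification
# ---------------------------------------------------------------------------

def build_cassette(design: LibraryDesign,
                   table: CodonTable | None = None) -> ConstructTemplate:
    """The full ribosome-display cassette for a design.

    Elements: promoter, RBS, ORF (ATG + scaffold codons with randomized
    slots), linker (SLEHHHHHH), spacer (stall region, stop-free in frame,
    embedding the RT-primer site), restriction-cassette (TolA-R2 reverse
    complement carrying the terminal BspQI site; not translated).
    """
    table = table or CodonTable.ecoli()
    # consensus protein: randomized slots carry their highest-weight letter
    orf = reverse_translate(design.consensus_protein(), table, design)
    orf_seq = "ATG" + orf.sequence
    linker_seq = table.encode(LINKER_PEPTIDE)
    spacer_seq = table.encode(SPACER_PEPTIDE_PREFIX) + revcomp(RT_PRIMER)
    terminal_seq = revcomp(TOLA_R2_PRIMER)
    parts = [
        ("promoter", PROMOTER_SEQ),
        ("RBS", RBS_SEQ),
        ("ORF", orf_seq),
        ("linker", linker_seq),
        ("spacer", spacer_seq),
        ("restriction-cassette", terminal_seq),
    ]
    elements, cursor = [], 0
    for name, seq in parts:
        elements.append(Element(name, cursor, cursor + len(seq)))
        cursor += len(seq)
    sequence = "".join(seq for _, seq in parts)
    orf_start = elements[2].start
    # cassette-coordinate slot offsets: +3 skips the prepended start codon
    slots = {pos: alts for pos, alts in orf.slots.items()}
    cassette_slots = {
        orf_start + 3 + 3 * pos: alts for pos, alts in slots.items()
    }
    return ConstructTemplate(sequence=sequence, elements=tuple(elements),
                             slots=cassette_slots)


@dataclass(frozen=True)
class CassetteReport:
    checks: dict[str, bool]
    warnings: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def verify_cassette(template: ConstructTemplate) -> CassetteReport:
    """Functional-unit verification of an assembled cassette.

    Asserts presence and order of the T7 promoter core, an RBS, an ORF with
    a start codon, the in-frame SLEHHHHHH linker, and the stall spacer;
    flags in-frame stop codons (through the spacer) and Type IIS sites
    inside the ORF as warnings.
    """
    seq = template.sequence
    checks: dict[str, bool] = {}
    warnings: list[str] = []

    t7_at = seq.find(T7_PROMOTER_CORE)
    checks["promoter"] = t7_at != -1

    orf_start = template.element("ORF").start if template.has_element("ORF") \
        else seq.find("ATG")
    rbs_region = seq[max(0, t7_at):orf_start] if t7_at != -1 else seq[:orf_start]
    checks["rbs"] = "AGGAG" in rbs_region and (t7_at == -1 or t7_at < orf_start)

    if template.has_element("ORF"):
        orf_seq = template.segment("ORF")
        checks["orf_start_codon"] = orf_seq.startswith("ATG")
        checks["orf_in_frame"] = len(orf_seq) % 3 == 0
        coding = orf_seq
        for extra in ("linker", "spacer"):
            if template.has_element(extra):
                coding += template.segment(extra)
        protein = translate(coding[: 3 * (len(coding) // 3)])
        checks["linker_in_frame"] = LINKER_PEPTIDE in protein
        if "*" in protein:
            warnings.append(
                f"in-frame stop codon at protein position {protein.index('*')}"
            )
        checks["no_internal_stop"] = "*" not in protein
        orf_el = template.element("ORF")
        for h in scan_restriction_sites(orf_seq):
            warnings.append(
                f"Type IIS {h.enzyme} site inside ORF at {orf_el.start + h.start} "
                f"({h.strand})"
            )
    else:
        checks["orf_start_codon"] = False
        checks["orf_in_frame"] = False
        checks["linker_in_frame"] = LINKER_PEPTIDE in translate(
            seq[: 3 * (len(seq) // 3)]
        )
        checks["no_internal_stop"] = False
    checks["spacer"] = template.has_element("spacer")
    return CassetteReport(checks=checks, warnings=tuple(warnings) + template.warnings)


# ---------------------------------------------------------------------------
# plain-text exports
# ---------------------------------------------------------------------------

def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def feature_table(template: ConstructTemplate) -> str:
    """GenBank-style plain-text feature table for the element map."""
    lines = ["element\tstart\tend\tlength"]
    for e in template.elements:
        lines.append(f"{e.name}\t{e.start}\t{e.end}\t{len(e)}")
    return "\n".join(lines) + "\n"
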