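"""Amplicon repertoire QC: anchored CDR extraction and composition checks.

Reads are matched against framework DNA anchors flanking each target region
(CDR1, CDR3).  A read yields an extraction for a region iff both anchors
match within a per-anchor mismatch budget, the intervening segment has
exactly the designed length, and it translates without stop codons;
otherwise the read gets a typed rejection (anchor-miss, length-miss,
frame-stop, or low-quality when a quality floor is set).  Matching is
strand-safe: a reverse-complemented read gives the identical extraction.

Observed per-position amino-acid frequencies are then compared with the
design using a relative-percent discrepancy |O - E| / E * 100, binned as
<10%, [10%, 20%), and >=20% (left-closed edges).  Residues observed at a
randomized position but absent from its designed set are reported as
off-design mass and excluded from the binning.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .assembly import CodonTable, ConstructTemplate, build_cassette, revcomp
from .design import LibraryDesign
from .simulate import ReadSet

_CODON_AA: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_AA:
        from Bio.Seq import Seq
        bases = "ACGT"
        for a in bases:
            for b in bases:
                for c in bases:
                    codon = a + b + c
                    _CODON_AA[codon] = str(Seq(codon).translate())
    return _CODON_AA


class QCError(ValueError):
    pass


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

MIN_ANCHOR_LEN = 12


@dataclass(frozen=True)
class RegionAnchor:
    """Framework anchors flanking one target region on the cassette."""

    region: str
    upstream: str                 # DNA immediately 5' of the region
    downstream: str               # DNA immediately 3' of the region
    upstream_start: int           # cassette coordinate of the upstream anchor
    region_nt_length: int
    protein_start: int            # design coordinate of the region start
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        if min(len(self.upstream), len(self.downstream)) < MIN_ANCHOR_LEN:
            raise QCError(
                f"{self.region}: anchors must be >= {MIN_ANCHOR_LEN} nt"
            )
        if self.max_mismatch < 0:
            raise QCError("max_mismatch must be >= 0")


@dataclass(frozen=True)
class AnchorSet:
    anchors: tuple[RegionAnchor, ...]

    def __iter__(self) -> Iterator[RegionAnchor]:
        return iter(self.anchors)

    def region(self, name: str) -> RegionAnchor:
        for a in self.anchors:
            if a.region == name:
                return a
        raise QCError(f"no anchors for region {name!r}")


def default_anchors(design: LibraryDesign,
                    template: ConstructTemplate | None = None,
                    regions: Sequence[str] = ("CDR1", "CDR3"),
                    anchor_len: int = 15,
                    max_mismatch: int = 2) -> AnchorSet:
    """Framework anchors derived from the design's cassette.

    Anchor windows must lie entirely in framework (no randomized codon
    slots), which holds for CDR-flanking framework by construction.
    """
    template = template or build_cassette(design)
    orf_start = template.element("ORF").start
    slot_nts = {
        off + k for off in template.slots for k in range(3)
    }
    anchors = []
    for name in regions:
        region = design.region(name)
        nt_start = orf_start + 3 + 3 * region.start
        nt_end = orf_start + 3 + 3 * region.end
        up = template.sequence[nt_start - anchor_len:nt_start]
        down = template.sequence[nt_end:nt_end + anchor_len]
        window = set(range(nt_start - anchor_len, nt_start)) | \
            set(range(nt_end, nt_end + anchor_len))
        if window & slot_nts:
            raise QCError(
                f"{name}: anchor window overlaps randomized codons; "
                "use a shorter anchor or different region bounds"
            )
        anchors.append(RegionAnchor(
            region=name, upstream=up, downstream=down,
            upstream_start=nt_start - anchor_len,
            region_nt_length=nt_end - nt_start,
            protein_start=region.start,
            max_mismatch=max_mismatch,
        ))
    return AnchorSet(tuple(anchors))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtractedCDR:
    read_id: str
    region: str
    residues: str                 # protein residues across the whole region
    protein_start: int            # design coordinate of residues[0]
    anchor_mismatches: tuple[int, int]

    def residue_at(self, position: int) -> str:
        return self.residues[position - self.protein_start]


@dataclass(frozen=True)
class Rejection:
    read_id: str
    region: str | None
    reason: str                   # anchor-miss | length-miss | frame-stop | low-quality


def _hamming(a: str, b: str, budget: int) -> int:
    """Mismatch count, or budget+1 as soon as the budget is exceeded."""
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > budget:
                return m
    return m


def _candidate_offsets(seq: str, anchor: str, budget: int) -> list[int]:
    """Pigeonhole seed positions: split the anchor into budget+1 chunks; any
    match within budget must contain one exact chunk."""
    n_chunks = budget + 1
    L = len(anchor)
    chunk = L // n_chunks
    cands: set[int] = set()
    for k in range(n_chunks):
        lo = k * chunk
        hi = L if k == n_chunks - 1 else lo + chunk
        piece = anchor[lo:hi]
        i = seq.find(piece)
        while i != -1:
            off = i - lo
            if 0 <= off <= len(seq) - L:
                cands.add(off)
            i = seq.find(piece, i + 1)
    return sorted(cands)


def _match_region(seq: str, anchor: RegionAnchor) -> tuple[int, int, int] | None:
    """(segment start, up mismatches, down mismatches) or None."""
    up, down = anchor.upstream, anchor.downstream
    budget = anchor.max_mismatch
    seg = anchor.region_nt_length
    need = len(up) + seg + len(down)
    if len(seq) < need:
        return None

    def check(off: int) -> tuple[int, int, int] | None:
        if off < 0 or off + need > len(seq):
            return None
        mu = _hamming(seq[off:off + len(up)], up, budget)
        if mu > budget:
            return None
        dstart = off + len(up) + seg
        md = _hamming(seq[dstart:dstart + len(down)], down, budget)
        if md > budget:
            return None
        return off + len(up), mu, md

    # exact-find fast path, then pigeonhole-seeded mismatch scan
    i = seq.find(up)
    while i != -1:
        hit = check(i)
        if hit:
            return hit
        i = seq.find(up, i + 1)
    for off in _candidate_offsets(seq, up, budget):
        hit = check(off)
        if hit:
            return hit
    return None


def _iter_read_records(reads) -> Iterator[tuple[str, str, str | None]]:
    """Normalize supported read inputs to (id, sequence, quality)."""
    if isinstance(reads, ReadSet):
        for rid, r1, r2, qual in reads.records():
            yield f"{rid}/1", r1, qual
            yield f"{rid}/2", r2, qual
        return
    for rec in reads:
        if len(rec) == 2:
            rid, seq = rec
            yield rid, seq, None
        else:
            rid, seq, qual = rec[:3]
            yield rid, seq, qual


def read_pairs_from_fastq(r1_path: str | Path,
                          r2_path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream mate records from a FASTQ pair (gzip accepted)."""
    import pysam
    with pysam.FastxFile(str(r1_path)) as f1, \
            pysam.FastxFile(str(r2_path)) as f2:
        for i, (a, b) in enumerate(zip(f1, f2)):
            if a.sequence is None or b.sequence is None:
                raise QCError(f"unreadable FASTQ record at index {i}")
            yield f"{a.name}/1", a.sequence, a.quality
            yield f"{b.name}/2", b.sequence, b.quality


def extract_cdrs(reads, design: LibraryDesign,
                 anchors: AnchorSet | None = None,
                 min_quality: int = 0
                 ) -> tuple[list[ExtractedCDR], list[Rejection]]:
    """Framework-anchored CDR extraction with a typed rejection log.

    ``reads`` may be a :class:`~sybodykit.simulate.ReadSet`, an iterable of
    (id, sequence[, quality]) tuples, or the generator returned by
    :func:`read_pairs_from_fastq`.  Both strands are tried.  With
    ``min_quality`` > 0, a read whose quality string contains any base below
    the floor is rejected outright (low-quality).
    """
    anchors = anchors or default_anchors(design)
    codon_aa = _codon_table()
    extractions: list[ExtractedCDR] = []
    rejections: list[Rejection] = []
    for rid, seq, qual in _iter_read_records(reads):
        if min_quality > 0 and qual:
            floor = chr(33 + min_quality)
            if any(q < floor for q in qual):
                rejections.append(Rejection(rid, None, "low-quality"))
                continue
        seq = seq.upper()
        strands = (seq, revcomp(seq))
        matched_any = False
        typed: Rejection | None = None
        for anchor in anchors:
            hit = None
            for s in strands:
                hit = _match_region(s, anchor)
                if hit:
                    strand_seq = s
                    break
            if not hit:
                continue
            seg_start, mu, md = hit
            segment = strand_seq[seg_start:seg_start + anchor.region_nt_length]
            if len(segment) != anchor.region_nt_length:
                typed = Rejection(rid, anchor.region, "length-miss")
                continue
            protein = "".join(
                codon_aa[segment[i:i + 3]]
                for i in range(0, len(segment), 3)
            )
            if "*" in protein:
                typed = Rejection(rid, anchor.region, "frame-stop")
                continue
            extractions.append(ExtractedCDR(
                read_id=rid, region=anchor.region, residues=protein,
                protein_start=anchor.protein_start,
                anchor_mismatches=(mu, md),
            ))
            matched_any = True
        if not matched_any:
            rejections.append(typed or Rejection(rid, None, "anchor-miss"))
    return extractions, rejections


# ---------------------------------------------------------------------------
# frequency tables & discrepancy
# ---------------------------------------------------------------------------

def observed_frequencies(extractions: Sequence[ExtractedCDR],
                         design: LibraryDesign) -> pd.DataFrame:
    """Observed per-(randomized position, amino acid) frequencies.

    frequency = count / extractions covering the position.  Residues outside
    the designed allowed set appear with ``designed`` False (off-design
    mass, e.g. sequencing errors); they share the same denominator.
    """
    if not extractions:
        raise QCError("no extractions to tabulate")
    by_region: dict[str, list[ExtractedCDR]] = {}
    for ex in extractions:
        by_region.setdefault(ex.region, []).append(ex)
    rows = []
    for region_name, exs in by_region.items():
        region = design.region(region_name)
        positions = [p for p in design.randomized_positions if p in region]
        mat = np.array(
            [np.frombuffer(ex.residues.encode(), dtype=np.uint8) for ex in exs]
        )
        total = len(exs)
        for pos in positions:
            col = mat[:, pos - region.start]
            letters, counts = np.unique(col, return_counts=True)
            allowed = set(design.composition_at(pos).weights)
            comp = design.composition_at(pos)
            for code, count in zip(letters, counts):
                aa = chr(code)
                rows.append({
                    "position": pos,
                    "display_number": comp.display_number,
                    "region": region_name,
                    "amino_acid": aa,
                    "frequency": count / total,
                    "count": int(count),
                    "designed": aa in allowed,
                })
    df = pd.DataFrame(rows).sort_values(
        ["position", "amino_acid"], ignore_index=True
    )
    df["label"] = "observed"
    return df


BIN_LT10 = "<10%"
BIN_10_20 = "10-20%"
BIN_GT20 = ">20%"


def _bin_of(disc: float) -> str:
    if disc < 10.0:
        return BIN_LT10
    if disc < 20.0:
        return BIN_10_20
    return BIN_GT20


@dataclass(frozen=True)
class DiscrepancyReport:
    """Per-composition discrepancies plus per-region bin summaries."""

    table: pd.DataFrame           # one row per designed composition
    summary: pd.DataFrame         # one row per region
    off_design: pd.DataFrame      # observed but undesigned residues


def discrepancy_report(observed: pd.DataFrame,
                       expected: pd.DataFrame) -> DiscrepancyReport:
    """Compare observed vs expected composition frequencies.

    discrepancy = |observed - expected| / expected * 100 (relative percent).
    A designed composition with zero observed reads is unrepresented
    (represented False, no bin).  Bin counts per region therefore sum to the
    number of represented designed compositions.  Only regions present in
    the observed table are compared (with PE150 amplicons CDR2 is never
    sequenced, so its compositions are not scored as unrepresented).
    """
    covered = set(observed["region"].unique())
    expected = expected[expected["region"].isin(covered)]
    exp = expected.rename(columns={"frequency": "expected_frequency"})
    obs_designed = observed[observed.get("designed", True)].rename(
        columns={"frequency": "observed_frequency"}
    )
    merged = exp.merge(
        obs_designed[["position", "amino_acid", "observed_frequency", "count"]],
        on=["position", "amino_acid"], how="left",
    )
    merged["count"] = merged["count"].fillna(0).astype(int)
    merged["observed_frequency"] = merged["observed_frequency"].fillna(0.0)
    if (merged["expected_frequency"] <= 0).any():
        raise QCError("expected frequency 0 for a designed composition")
    merged["discrepancy_pct"] = (
        (merged["observed_frequency"] - merged["expected_frequency"]).abs()
        / merged["expected_frequency"] * 100.0
    )
    merged["represented"] = merged["count"] > 0
    merged["bin"] = [
        _bin_of(d) if rep else None
        for d, rep in zip(merged["discrepancy_pct"], merged["represented"])
    ]
    summaries = []
    for region, grp in merged.groupby("region", sort=False):
        summaries.append({
            "region": region,
            "n_compositions": len(grp),
            "represented": int(grp["represented"].sum()),
            "unrepresented": int((~grp["represented"]).sum()),
            "bin_lt10": int((grp["bin"] == BIN_LT10).sum()),
            "bin_10_20": int((grp["bin"] == BIN_10_20).sum()),
            "bin_gt20": int((grp["bin"] == BIN_GT20).sum()),
        })
    off = observed[~observed.get("designed", pd.Series(True, index=observed.index))]
    off_summary = (
        off.groupby("position")["frequency"].sum().rename("off_design_mass")
        .reset_index()
        if len(off) else pd.DataFrame(columns=["position", "off_design_mass"])
    )
    return DiscrepancyReport(
        table=merged,
        summary=pd.DataFrame(summaries),
        off_design=off_summary,
    )


# ---------------------------------------------------------------------------
# clonotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClonotypeTable:
    """CDR1+CDR3 amino-acid clonotypes from paired extractions."""

    table: pd.DataFrame           # columns cdr1, cdr3, count
    total: int
    unique_fraction: float
    dropped: int                  # reads lacking one of the two regions


def _base_id(read_id: str) -> str:
    if read_id.endswith(("/1", "/2")):
        return read_id[:-2]
    return read_id


def clonotype_stats(extractions: Sequence[ExtractedCDR]) -> ClonotypeTable:
    """Pair CDR1 and CDR3 extractions by read id and count clonotypes.

    The clonotype key is the (CDR1 residues, CDR3 residues) amino-acid pair;
    unique fraction = distinct keys / total assembled pairs.  Reads with
    only one of the two regions are dropped and counted.
    """
    cdr1: dict[str, str] = {}
    cdr3: dict[str, str] = {}
    for ex in extractions:
        bucket = cdr1 if ex.region == "CDR1" else cdr3 if ex.region == "CDR3" \
            else None
        if bucket is not None:
            bucket[_base_id(ex.read_id)] = ex.residues
    paired = sorted(set(cdr1) & set(cdr3))
    dropped = len(set(cdr1) ^ set(cdr3))
    counts: dict[tuple[str, str], int] = {}
    for rid in paired:
        key = (cdr1[rid], cdr3[rid])
        counts[key] = counts.get(key, 0) + 1
    table = pd.DataFrame(
        [{"cdr1": k[0], "cdr3": k[1], "count": v} for k, v in counts.items()],
        columns=["cdr1", "cdr3", "count"],
    ).sort_values("count", ascending=False, ignore_index=True)
    total = len(paired)
    unique_fraction = (len(counts) / total) if total else 0.0
    return ClonotypeTable(table=table, total=total,
                          unique_fraction=unique_fraction, dropped=dropped)
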