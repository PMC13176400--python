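"""Synthetic inputs for the pipeline: variant libraries, PE150 amplicon
reads, BLI sensorgrams, and two-condition ELISA plates.

Every generator is a pure function of its parameters and seed, so reruns are
byte-identical.  The read simulator emulates paired-end 150 bp amplicon
sequencing of the display cassette: read 1 starts at the forward amplicon
end and covers CDR1, read 2 at the reverse end and covers CDR3; with the
default amplicon (ORF start through the SLEHHHHHH linker, 396 nt) the CDR2
segment falls in the unsequenced middle gap, matching a CDR1/CDR3-only
analysis.  Errors are i.i.d. substitutions; indels are not modeled (a
fixed-length amplicon extractor would reject them anyway).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from . import kinetics as _kinetics
from .assembly import CodonTable, ConstructTemplate, build_cassette
from .design import LibraryDesign

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP[_a] = _b
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _BASE_INDEX[_a] = _i


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# variant sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasModel:
    """Multiplicative enrichment factors on design weights.

    ``factors`` maps (position, amino_acid) to a strictly positive factor
    applied before per-position renormalization; unlisted pairs keep factor
    1.  ``substitution_rate`` optionally records the per-base error rate the
    accompanying read simulation should use.
    """

    factors: Mapping[tuple[int, str], float] = field(default_factory=dict)
    substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        for key, f in self.factors.items():
            if not (f > 0):
                raise SimulationError(f"bias factor for {key} must be positive")

    def weights_at(self, position: int,
                   weights: Mapping[str, float]) -> dict[str, float]:
        raw = {
            aa: w * self.factors.get((position, aa), 1.0)
            for aa, w in weights.items()
        }
        total = sum(raw.values())
        return {aa: w / total for aa, w in raw.items()}


@dataclass(frozen=True)
class VariantSample:
    """One sampled library member."""

    protein: str
    dna: str                      # full cassette DNA
    residues: dict[int, str]      # randomized position -> sampled letter
    count: int = 1                # copy count (PCR duplication handle)


def sample_variants(design: LibraryDesign, n: int,
                    bias: BiasModel | None = None, seed: int = 0,
                    table: CodonTable | None = None,
                    template: ConstructTemplate | None = None
                    ) -> list[VariantSample]:
    """Draw ``n`` library variants, each randomized position independent.

    Weights come from the design, optionally reshaped by ``bias`` and
    renormalized.  The returned variants carry full cassette DNA built from
    the (shared) construct template.
    """
    if n < 0:
        raise SimulationError(f"n must be >= 0, got {n}")
    table = table or CodonTable.ecoli()
    template = template or build_cassette(design, table)
    rng = np.random.default_rng(seed)
    if n == 0:
        return []

    positions = design.randomized_positions
    scaffold = np.frombuffer(design.scaffold.encode(), dtype=np.uint8)
    proteins = np.tile(scaffold, (n, 1))
    cassette = np.frombuffer(template.sequence.encode(), dtype=np.uint8)
    dnas = np.tile(cassette, (n, 1))
    orf_start = template.element("ORF").start

    sampled: dict[int, np.ndarray] = {}
    for pos in positions:
        comp = design.composition_at(pos)
        weights = dict(comp.weights)
        if bias is not None:
            weights = bias.weights_at(pos, weights)
        letters = comp.letters
        probs = np.array([weights[a] for a in letters], dtype=float)
        probs /= probs.sum()
        idx = rng.choice(len(letters), size=n, p=probs)
        sampled[pos] = idx
        letter_bytes = np.frombuffer("".join(letters).encode(), dtype=np.uint8)
        proteins[:, pos] = letter_bytes[idx]
        codons = np.array(
            [np.frombuffer(table.codon_of[a].encode(), dtype=np.uint8)
             for a in letters]
        )
        off = orf_start + 3 + 3 * pos   # +3 skips the prepended start codon
        dnas[:, off:off + 3] = codons[idx]

    variants = []
    letter_lists = {
        pos: design.composition_at(pos).letters for pos in positions
    }
    for i in range(n):
        residues = {pos: letter_lists[pos][sampled[pos][i]] for pos in positions}
        variants.append(
            VariantSample(
                protein=proteins[i].tobytes().decode(),
                dna=dnas[i].tobytes().decode(),
                residues=residues,
            )
        )
    return variants


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSet:
    """Paired reads with constant qualities and per-read provenance."""

    ids: tuple[str, ...]
    read1: tuple[str, ...]
    read2: tuple[str, ...]
    source: tuple[int, ...]       # index of the originating variant
    quality_char: str
    seed: int

    def __len__(self) -> int:
        return len(self.ids)

    def records(self) -> Iterator[tuple[str, str, str, str]]:
        """Yield (read_id, mate1 sequence, mate2 sequence, quality string)."""
        q1 = self.quality_char * (len(self.read1[0]) if self.read1 else 0)
        for rid, r1, r2 in zip(self.ids, self.read1, self.read2):
            yield rid, r1, r2, q1

    def write_fastq(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        p1 = prefix.with_name(prefix.name + "_R1.fastq")
        p2 = prefix.with_name(prefix.name + "_R2.fastq")
        for path, seqs, mate in ((p1, self.read1, 1), (p2, self.read2, 2)):
            with open(path, "w") as fh:
                for rid, seq in zip(self.ids, seqs):
                    fh.write(f"@{rid}/{mate}\n{seq}\n+\n"
                             f"{self.quality_char * len(seq)}\n")
        return p1, p2


def amplicon_bounds(template: ConstructTemplate) -> tuple[int, int]:
    """Default sequenced amplicon: ORF start through the linker end."""
    return template.element("ORF").start, template.element("linker").end


def simulate_reads(variants: Sequence[VariantSample], depth: int,
                   error_rate: float = 0.0, seed: int = 0,
                   template: ConstructTemplate | None = None,
                   design: LibraryDesign | None = None,
                   read_length: int = 150,
                   amplicon: tuple[int, int] | None = None,
                   quality: int = 40,
                   with_replacement: bool = True) -> ReadSet:
    """Paired-end reads from the variant cassettes.

    Sampling probability is proportional to each variant's copy count;
    substitution errors are i.i.d. per base at ``error_rate``.  The amplicon
    defaults to ORF start .. linker end of the construct template (built
    from ``design`` when not supplied).  ``with_replacement`` False draws
    each read from a distinct molecule (no PCR duplication), requiring
    ``depth <= len(variants)``.
    """
    if depth < 0:
        raise SimulationError("depth must be >= 0")
    if not (0 <= error_rate < 1):
        raise SimulationError("error_rate must be in [0, 1)")
    if depth and not variants:
        raise SimulationError("no variants to sequence")
    if amplicon is None:
        if template is None:
            if design is None:
                raise SimulationError(
                    "provide a template, a design, or explicit amplicon bounds"
                )
            template = build_cassette(design)
        amplicon = amplicon_bounds(template)
    start, end = amplicon
    if end - start < read_length:
        raise SimulationError(
            f"amplicon length {end - start} is shorter than the read length "
            f"{read_length}"
        )
    qchar = chr(33 + quality)
    if depth == 0:
        return ReadSet((), (), (), (), qchar, seed)
    for v in variants:
        if len(v.dna) < end:
            raise SimulationError(
                "variant cassette shorter than the amplicon end"
            )

    rng = np.random.default_rng(seed)
    counts = np.array([v.count for v in variants], dtype=float)
    if with_replacement:
        idx = rng.choice(len(variants), size=depth, p=counts / counts.sum())
    else:
        if depth > len(variants):
            raise SimulationError(
                "depth exceeds the variant pool for replacement-free sampling"
            )
        idx = rng.permutation(len(variants))[:depth]

    ampl = np.array(
        [np.frombuffer(v.dna.encode(), dtype=np.uint8)[start:end]
         for v in variants]
    )
    r1 = ampl[idx, :read_length].copy()
    r2 = _COMP[ampl[idx, -read_length:]][:, ::-1].copy()
    for mat in (r1, r2):
        if error_rate > 0:
            hit = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=mat.shape)
            new = _BASES[(_BASE_INDEX[mat] + shift) % 4]
            mat[hit] = new[hit]
        else:
            # keep the random stream layout stable across error settings
            pass

    ids = tuple(f"sim{i} variant={j}" for i, j in enumerate(idx))
    return ReadSet(
        ids=ids,
        read1=tuple(row.tobytes().decode() for row in r1),
        read2=tuple(row.tobytes().decode() for row in r2),
        source=tuple(int(j) for j in idx),
        quality_char=qchar,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sensorgrams
# ---------------------------------------------------------------------------

def simulate_sensorgrams(kon: float, koff: float, rmax: float,
                         concentrations: Sequence[float],
                         t_association: float = 300.0,
                         t_dissociation: float = 600.0,
                         dt: float = 1.0,
                         noise: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Noisy 1:1-binding sensorgrams at several analyte concentrations.

    Closed-form association/dissociation responses (see
    :func:`sybodykit.kinetics.model_response`) with additive Gaussian noise
    of standard deviation ``noise`` (response units).  Returns a tidy frame
    with columns concentration, phase, time, response; dissociation times
    continue after the association phase.
    """
    if kon <= 0 or koff < 0 or rmax <= 0:
        raise SimulationError("require kon > 0, koff >= 0, rmax > 0")
    if any(c <= 0 for c in concentrations):
        raise SimulationError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    t_a = np.arange(0.0, t_association + dt / 2, dt)
    t_d = np.arange(t_association, t_association + t_dissociation + dt / 2, dt)
    for conc in concentrations:
        y_a = _kinetics.model_response(kon, koff, rmax, conc, t_a,
                                       phase="association")
        r0 = float(y_a[-1])
        y_d = _kinetics.model_response(kon, koff, rmax, conc, t_d,
                                       phase="dissociation", r0=r0,
                                       t0=t_association)
        for phase, t, y in (("association", t_a, y_a),
                            ("dissociation", t_d, y_d)):
            y = y + (rng.normal(0.0, noise, size=y.shape) if noise > 0 else 0.0)
            frames.append(pd.DataFrame({
                "concentration": conc,
                "phase": phase,
                "time": t,
                "response": y,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# ELISA plates
# ---------------------------------------------------------------------------

CALCIUM = "calcium"
CHELATOR = "chelator"


def simulate_elisa(n_clones: int = 96, binder_fraction: float = 0.5,
                   binder_log_ratio_mean: float = float(np.log(3.0)),
                   binder_log_ratio_sd: float = 0.25,
                   null_log_ratio_sd: float = 0.08,
                   base_signal: float = 0.30,
                   noise: float = 0.02, seed: int = 0) -> pd.DataFrame:
    """Two-condition ELISA plate with a binder/non-binder mixture.

    Binder clones draw their calcium/chelator signal ratio from a lognormal
    distribution centered at ``exp(binder_log_ratio_mean)`` (default 3x);
    non-binders from a lognormal null centered at ratio 1.  Signals are
    absorbance-like, non-negative.  Columns: clone, condition, signal.
    """
    if not (0 <= binder_fraction <= 1):
        raise SimulationError("binder_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_binders = int(round(n_clones * binder_fraction))
    is_binder = np.zeros(n_clones, dtype=bool)
    is_binder[:n_binders] = True
    rng.shuffle(is_binder)
    log_ratio = np.where(
        is_binder,
        rng.normal(binder_log_ratio_mean, binder_log_ratio_sd, n_clones),
        rng.normal(0.0, null_log_ratio_sd, n_clones),
    )
    chelator = np.clip(
        base_signal * (1.0 + rng.normal(0.0, noise, n_clones)), 1e-6, None
    )
    calcium = np.exp(log_ratio) * chelator
    rows = []
    for i in range(n_clones):
        clone = f"clone{i + 1:03d}"
        rows.append({"clone": clone, "condition": CALCIUM,
                     "signal": float(calcium[i])})
        rows.append({"clone": clone, "condition": CHELATOR,
                     "signal": float(chelator[i])})
    return pd.DataFrame(rows)
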