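"""Semi-randomized nanobody library designs.

A :class:`LibraryDesign` couples a VHH scaffold protein with a region map
(FR1..FR4 framework segments and CDR1/2/3, where each CDR includes its
randomized flanking positions) and a set of per-position randomization
compositions.  A composition assigns a weight (design frequency) to each
allowed amino acid at one scaffold position; non-randomized positions are
fixed to the scaffold letter.

The module also provides the library diversity arithmetic: a fully
randomized stretch of ``n`` positions over an alphabet of ``a`` letters
encodes ``a**n`` distinct sequences, and a semi-randomized design encodes
the product of its per-position allowed-set sizes (weights change sampling
frequencies, not the count of encodable sequences).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: 18-letter alphabet used for "fully randomized" positions: all standard
#: amino acids except cysteine (disulfide risk) and proline (backbone rigidity).
FULL_RANDOM_ALPHABET = "ADEFGHIKLMNQRSTVWY"

_WEIGHT_TOL = 1e-9


class DesignError(ValueError):
    """Base class for design-spec problems."""


class DesignParseError(DesignError):
    """The design file could not be interpreted (missing/ill-typed field)."""


class DesignValidationError(DesignError):
    """The design parsed but violates a structural invariant."""


@dataclass(frozen=True)
class ResidueComposition:
    """Allowed amino acids and their design weights at one scaffold position.

    ``position`` is a 0-based index into the scaffold protein.
    ``display_number`` carries the figure-style residue number, if any.
    """

    position: int
    weights: Mapping[str, float]
    display_number: int | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise DesignValidationError(f"negative position {self.position}")
        if not self.weights:
            raise DesignValidationError(
                f"position {self.position}: empty allowed set"
            )
        for aa, w in self.weights.items():
            if aa not in AMINO_ACIDS or len(aa) != 1:
                raise DesignValidationError(
                    f"position {self.position}: {aa!r} is not a standard amino acid"
                )
            if not (w > 0):
                raise DesignValidationError(
                    f"position {self.position}: weight for {aa} must be positive"
                )
        total = sum(self.weights.values())
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise DesignValidationError(
                f"position {self.position}: weights sum to {total!r}, expected 1"
            )

    @property
    def letters(self) -> tuple[str, ...]:
        """Allowed letters, highest weight first (alphabetical tie-break)."""
        return tuple(sorted(self.weights, key=lambda a: (-self.weights[a], a)))

    @property
    def consensus(self) -> str:
        return self.letters[0]

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class Region:
    """A named scaffold segment in 0-based half-open protein coordinates."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise DesignValidationError(
                f"region {self.name}: bad span [{self.start}, {self.end})"
            )

    def __contains__(self, position: int) -> bool:
        return self.start <= position < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Diversity:
    """Count of distinct sequences a design can encode (dimensionless)."""

    value: int

    def __post_init__(self) -> None:
        if self.value < 1:
            raise DesignValidationError("diversity must be >= 1")

    def __int__(self) -> int:
        return self.value

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class LibraryDesign:
    scaffold: str
    regions: tuple[Region, ...]
    compositions: tuple[ResidueComposition, ...]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "compositions", tuple(self.compositions))
        n = len(self.scaffold)
        if n == 0:
            raise DesignValidationError("empty scaffold")
        bad = [c for c in self.scaffold if c not in AMINO_ACIDS]
        if bad:
            raise DesignValidationError(f"non-standard scaffold letters: {bad}")
        # regions: ordered, non-overlapping, covering the scaffold
        cursor = 0
        for r in self.regions:
            if r.start != cursor:
                raise DesignValidationError(
                    f"region {r.name} starts at {r.start}, expected {cursor} "
                    "(regions must be ordered, contiguous and cover the scaffold)"
                )
            cursor = r.end
        if cursor != n:
            raise DesignValidationError(
                f"regions cover [0, {cursor}) but scaffold has length {n}"
            )
        seen: set[int] = set()
        for c in self.compositions:
            if c.position >= n:
                raise DesignValidationError(
                    f"composition position {c.position} outside scaffold (len {n})"
                )
            if c.position in seen:
                raise DesignValidationError(
                    f"duplicate composition at position {c.position}"
                )
            seen.add(c.position)

    # -- lookups ---------------------------------------------------------

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise DesignError(
            f"unknown region {name!r}; have {[r.name for r in self.regions]}"
        )

    @property
    def randomized_positions(self) -> tuple[int, ...]:
        return tuple(sorted(c.position for c in self.compositions))

    def composition_at(self, position: int) -> ResidueComposition:
        for c in self.compositions:
            if c.position == position:
                return c
        raise DesignError(f"position {position} is not randomized")

    def compositions_in(self, region_name: str) -> tuple[ResidueComposition, ...]:
        region = self.region(region_name)
        return tuple(
            c for c in sorted(self.compositions, key=lambda c: c.position)
            if c.position in region
        )

    def consensus_protein(self) -> str:
        """Scaffold with each randomized position at its highest-weight letter."""
        letters = list(self.scaffold)
        for c in self.compositions:
            letters[c.position] = c.consensus
        return "".join(letters)


# ---------------------------------------------------------------------------
# loading / export
# ---------------------------------------------------------------------------

def _parse_allowed(raw: object, position: int) -> dict[str, float]:
    if isinstance(raw, Mapping):
        return {str(k): float(v) for k, v in raw.items()}
    if isinstance(raw, (list, tuple)):
        n = len(raw)
        if n == 0:
            raise DesignParseError(f"position {position}: empty allowed list")
        return {str(a): 1.0 / n for a in raw}
    raise DesignParseError(
        f"position {position}: 'allowed' must be a mapping or list, got {type(raw).__name__}"
    )


def design_from_dict(doc: Mapping) -> LibraryDesign:
    """Build a validated design from a parsed JSON/YAML document."""
    try:
        scaffold = str(doc["scaffold"])
        raw_regions = doc["regions"]
        raw_comps = doc.get("compositions", [])
    except (KeyError, TypeError) as exc:
        raise DesignParseError(f"missing required field: {exc}") from exc
    regions = []
    for r in raw_regions:
        try:
            regions.append(Region(str(r["name"]), int(r["start"]), int(r["end"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise DesignParseError(f"malformed region entry {r!r}: {exc}") from exc
    comps = []
    for c in raw_comps:
        try:
            pos = int(c["position"])
            allowed = _parse_allowed(c["allowed"], pos)
            disp = c.get("display_number")
        except (KeyError, TypeError, ValueError) as exc:
            raise DesignParseError(f"malformed composition entry {c!r}: {exc}") from exc
        comps.append(
            ResidueComposition(pos, allowed, None if disp is None else int(disp))
        )
    return LibraryDesign(
        scaffold=scaffold,
        regions=tuple(regions),
        compositions=tuple(comps),
        name=str(doc.get("name", "unnamed")),
    )


def load_design(path: str | Path) -> LibraryDesign:
    """Load and validate a design-spec file (YAML or JSON)."""
    path = Path(path)
    text = path.read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise DesignParseError(f"{path}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise DesignParseError(f"{path}: top level must be a mapping")
    return design_from_dict(doc)


def load_s10() -> LibraryDesign:
    """The packaged S1.0 design fixture (synthetic reconstruction)."""
    with resources.files("sybodykit.data").joinpath("s1_0.yaml").open() as fh:
        return design_from_dict(yaml.safe_load(fh))


def scaffold_to_fasta(design: LibraryDesign, path: str | Path,
                      consensus: bool = False) -> None:
    """Write the scaffold (or consensus) protein as FASTA."""
    seq = design.consensus_protein() if consensus else design.scaffold
    label = f"{design.name}{'_consensus' if consensus else '_scaffold'}"
    Path(path).write_text(f">{label}\n{seq}\n")


# ---------------------------------------------------------------------------
# diversity arithmetic
# ---------------------------------------------------------------------------

def fully_randomized_diversity(n_positions: int, alphabet_size: int) -> Diversity:
    """Exact diversity ``alphabet_size ** n_positions`` of full randomization."""
    if n_positions < 0:
        raise DesignError(f"n_positions must be >= 0, got {n_positions}")
    if alphabet_size < 1:
        raise DesignError(f"alphabet_size must be >= 1, got {alphabet_size}")
    return Diversity(alphabet_size ** n_positions)


def theoretical_diversity(design: LibraryDesign) -> Diversity:
    """Product over randomized positions of the allowed-set size.

    Weights shift sampling frequencies but not the count of encodable
    sequences, so only set sizes enter.
    """
    value = 1
    for c in design.compositions:
        value *= len(c)
    return Diversity(value)


def expected_frequencies(design: LibraryDesign) -> pd.DataFrame:
    """Per-(position, amino acid) design frequencies as a tidy table.

    One row per designed composition pair; rows for a position sum to 1.
    """
    rows = []
    for c in sorted(design.compositions, key=lambda c: c.position):
        region = next(r.name for r in design.regions if c.position in r)
        for aa in c.letters:
            rows.append(
                {
                    "position": c.position,
                    "display_number": c.display_number,
                    "region": region,
                    "amino_acid": aa,
                    "frequency": c.weights[aa],
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["position", "display_number", "region", "amino_acid", "frequency"],
    )
    df["label"] = "expected"
    return df


def composition_count(design: LibraryDesign, region_name: str) -> int:
    """Number of designed (position, amino acid) pairs in a region.

    CDR regions include their randomized flanking positions, which the
    region map already attaches to the adjacent CDR.
    """
    return sum(len(c) for c in design.compositions_in(region_name))
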