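"""Chromosomal arrangements of the *D. subobscura* E chromosome.

An arrangement is an ordered, proximal-to-distal (centromere outward) list of
oriented fragments drawn from a fixed alphabet.  The named fragments are the
sections that flank the breakpoints of the overlapping inversions E1, E2, E9,
E3 and E12: the shared A fragment (sections ``A_p`` and ``A_d``), the B part
(``B_p``, ``B_d``) and the distal partners ``G``, ``K``, ``L``, ``H2`` and
``F``.  Neutral filler fragments ``W1..Wn`` pad the rest of the chromosome so
that inversions have somewhere to put their breaks.

Breaks happen only at fragment boundaries: the fragments are atomic and the
inversions of interest are all specified between named sections, so no
nucleotide-level coordinates are modeled.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Named (non-filler) fragments.
NAMED_FRAGMENTS = frozenset({"A_p", "A_d", "B_p", "B_d", "G", "K", "L", "H2", "F"})

#: Allowed provenance labels.  ``BIR_copy`` is accepted for completeness but
#: break-induced-replication copies are tagged with the template lineage.
PROVENANCES = frozenset({"ancestral", "E_st", "E_1+2", "BIR_copy"})

_FILLER_RE = re.compile(r"^W\d+$")

#: Default fragment lengths (nt).  A_p + A_d approximate the ~2-kb sequenced
#: window of the A fragment; the full A_d section is ~9 kb but only the
#: sequenced window matters downstream.  B_p is the ~500-nt captured fragment.
DEFAULT_LENGTHS: dict[str, int] = {"A_p": 1000, "A_d": 1000, "B_p": 500}
_FALLBACK_LENGTH = 1000


class ArrangementError(ValueError):
    """Raised for malformed fragments, arrangements or break indices."""


@dataclass(frozen=True)
class Fragment:
    """One oriented chromosome fragment.

    ``provenance`` records which homologous lineage contributed the fragment
    at the E9 origin (``ancestral`` when the question does not arise);
    ``copy_id`` distinguishes duplicated copies of the same named fragment.
    """

    name: str
    length_nt: int = _FALLBACK_LENGTH
    orientation: str = "+"
    provenance: str = "ancestral"
    copy_id: int = 1

    def __post_init__(self) -> None:
        if self.name not in NAMED_FRAGMENTS and not _FILLER_RE.match(self.name):
            raise ArrangementError(f"unknown fragment name {self.name!r}")
        if self.length_nt <= 0:
            raise ArrangementError(f"fragment {self.name}: length must be positive")
        if self.orientation not in ("+", "-"):
            raise ArrangementError(f"fragment {self.name}: orientation must be + or -")
        if self.provenance not in PROVENANCES:
            raise ArrangementError(
                f"fragment {self.name}: unknown provenance {self.provenance!r}"
            )

    def flipped(self) -> "Fragment":
        return replace(self, orientation="-" if self.orientation == "+" else "+")

    @property
    def signed_name(self) -> str:
        suffix = "" if self.copy_id == 1 else f"#{self.copy_id}"
        sign = "" if self.orientation == "+" else "-"
        return f"{self.name}{suffix}{sign}"


@dataclass(frozen=True)
class Arrangement:
    """Ordered proximal-to-distal fragment list with a name."""

    name: str
    fragments: tuple[Fragment, ...]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ArrangementError(f"arrangement {self.name!r} is empty")
        keys = [(f.name, f.copy_id) for f in self.fragments]
        if len(set(keys)) != len(keys):
            raise ArrangementError(
                f"arrangement {self.name!r}: duplicate (name, copy_id) pair"
            )

    def __len__(self) -> int:
        return len(self.fragments)

    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fragments)

    def signature(self) -> tuple[tuple[str, str], ...]:
        """(name, orientation) sequence — the comparison unit for products."""
        return tuple((f.name, f.orientation) for f in self.fragments)

    def index_of_boundary(self, boundary: tuple[str, str]) -> int:
        """Split position k such that fragments k-1, k are named ``boundary``.

        The first matching adjacency (scanning proximal to distal) is used.
        """
        left, right = boundary
        for k in range(1, len(self.fragments)):
            if self.fragments[k - 1].name == left and self.fragments[k].name == right:
                return k
        raise ArrangementError(
            f"boundary {left}|{right} not found in arrangement {self.name!r}"
        )

    def fragment_multiset(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.fragments:
            counts[f.name] = counts.get(f.name, 0) + 1
        return counts


@dataclass(frozen=True)
class BreakpointRegion:
    """A named junction window spanning contiguous fragments."""

    name: str
    fragments: tuple[Fragment, ...]
    start: int  # index of first window fragment in the parent arrangement

    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fragments)


@dataclass(frozen=True)
class Karyotype:
    """The two homologous E chromosomes of one individual."""

    homolog_1: Arrangement
    homolog_2: Arrangement

    @property
    def is_heterokaryotypic(self) -> bool:
        return self.homolog_1.name != self.homolog_2.name


# ---------------------------------------------------------------------------
# Construction helpers

def _frag(name: str, orientation: str = "+", provenance: str = "ancestral",
          lengths: Mapping[str, int] | None = None) -> Fragment:
    table = dict(DEFAULT_LENGTHS)
    if lengths:
        table.update(lengths)
    return Fragment(
        name=name,
        length_nt=table.get(name, _FALLBACK_LENGTH),
        orientation=orientation,
        provenance=provenance,
    )


def assemble(name: str, fragments: Iterable[Fragment]) -> Arrangement:
    """Build an arrangement, renumbering copy_ids by order of appearance."""
    out: list[Fragment] = []
    seen: dict[str, int] = {}
    for f in fragments:
        seen[f.name] = seen.get(f.name, 0) + 1
        out.append(replace(f, copy_id=seen[f.name]))
    return Arrangement(name=name, fragments=tuple(out))


def invert_segment(arr: Arrangement, i: int, j: int, name: str | None = None) -> Arrangement:
    """Reverse fragments ``i..j`` (inclusive), flipping each orientation.

    An involution: applying the same inversion twice restores the input.
    """
    n = len(arr.fragments)
    if not (0 <= i <= j < n):
        raise ArrangementError(
            f"invert_segment indices ({i}, {j}) out of range for {n} fragments"
        )
    middle = tuple(f.flipped() for f in reversed(arr.fragments[i : j + 1]))
    new = arr.fragments[:i] + middle + arr.fragments[j + 1 :]
    return Arrangement(name=name or f"{arr.name}.inv[{i}:{j}]", fragments=new)


# ---------------------------------------------------------------------------
# Canonical arrangements

CANONICAL_NAMES = ("E_st", "E_1+2", "E_1+2+9", "E_1+2+9+3", "E_1+2+9+12")

# Fragment orders satisfying every adjacency constraint of the arrangement
# series.  F sits proximal to the K,L junction in both E_st and E_1+2 so that
# the two homologs are identical distal of the K|L break — the E9 distal
# breakpoint — which is what makes the three heterokaryotype origin models
# produce one and the same derived fragment order.
_E_ST_ORDER = ("A_p", "A_d", "B_p", "B_d", "W1", "G", "W2", "H2", "W3", "F", "K", "L", "W4")
_E_12_ORDER = (  # E_1+2 defined directly, not via mechanistic E1/E2
    ("A_p", "+"), ("A_d", "+"), ("G", "+"), ("W2", "+"), ("H2", "+"), ("W3", "+"),
    ("W1", "-"), ("B_d", "-"), ("B_p", "-"), ("F", "+"), ("K", "+"), ("L", "+"),
    ("W4", "+"),
)


def canonical_arrangements(
    lengths: Mapping[str, int] | None = None,
) -> dict[str, Arrangement]:
    """The five canonical arrangements of the Mediterranean E-chromosome series.

    ``E_1+2+9`` is built as the heterokaryotype-origin product (proximal A
    window provenance ``E_st``, inverted central segment provenance ``E_1+2``);
    ``E_1+2+9+3`` applies the E3 inversion between the B_p|K junction and past
    H2; ``E_1+2+9+12`` applies an interior inversion that leaves both E9
    breakpoint regions untouched.
    """
    e_st = assemble("E_st", (_frag(n, lengths=lengths) for n in _E_ST_ORDER))
    e_12 = assemble(
        "E_1+2", (_frag(n, o, lengths=lengths) for n, o in _E_12_ORDER)
    )

    # E_1+2+9: E_st proximal piece + inverted E_1+2 central + shared tail.
    k_prox_st = e_st.index_of_boundary(("B_p", "B_d"))
    k_prox_12 = e_12.index_of_boundary(("A_p", "A_d"))
    k_dist = e_12.index_of_boundary(("K", "L"))
    proximal = tuple(replace(f, provenance="E_st") for f in e_st.fragments[:k_prox_st])
    central = tuple(
        f.flipped()
        for f in reversed(
            tuple(replace(f, provenance="E_1+2") for f in e_12.fragments[k_prox_12:k_dist])
        )
    )
    tail = tuple(replace(f, provenance="E_st") for f in e_st.fragments[k_dist:])
    e_129 = assemble("E_1+2+9", proximal + central + tail)

    # E_1+2+9+3: invert from the B_p|K junction through H2.
    i_k = e_129.index_of_boundary(("B_p", "K"))
    i_h2 = next(i for i, f in enumerate(e_129.fragments) if f.name == "H2")
    e_1293 = invert_segment(e_129, i_k, i_h2, name="E_1+2+9+3")

    # E_1+2+9+12: invert an interior filler-bounded window (E12 does not
    # affect the E9 breakpoints).
    i_w = next(i for i, f in enumerate(e_129.fragments) if f.name == "W3")
    i_w2 = next(i for i, f in enumerate(e_129.fragments) if f.name == "W2")
    lo, hi = min(i_w, i_w2), max(i_w, i_w2)
    e_12912 = invert_segment(e_129, lo, hi, name="E_1+2+9+12")

    return {a.name: a for a in (e_st, e_12, e_129, e_1293, e_12912)}


# ---------------------------------------------------------------------------
# Breakpoint-region extraction

# Name patterns scanned (forward and reversed) over consecutive fragment
# names.  Longer windows are tried first so AK/AH2/AB take precedence over
# their sub-windows; the three-fragment AK/AH2 variants cover derived
# chromosomes that duplicated A_d without capturing B_p.
_REGION_PATTERNS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("AB", ("A_p", "A_d", "B_p", "B_d")),
    ("AK", ("A_p", "A_d", "B_p", "K")),
    ("AH2", ("A_p", "A_d", "B_p", "H2")),
    ("AK", ("A_p", "A_d", "K")),
    ("AH2", ("A_p", "A_d", "H2")),
    ("AG", ("A_p", "A_d", "G")),
    ("GAL", ("G", "A_d", "L")),
    ("KL", ("K", "L")),
    ("BF", ("B_p", "F")),
)


def breakpoint_regions(arr: Arrangement) -> list[BreakpointRegion]:
    """Extract every named junction window present in ``arr``.

    A pure function of the fragment order.  Adjacencies involving the A
    fragment (``A_p``/``A_d``) that match no known window are junction
    candidates we cannot name: they are omitted with a logged warning.
    """
    names = arr.names()
    n = len(names)
    found: list[BreakpointRegion] = []
    covered: set[int] = set()
    claimed: set[int] = set()  # positions claimed by an A-containing window
    for region_name, pattern in _REGION_PATTERNS:
        w = len(pattern)
        for start in range(n - w + 1):
            window = names[start : start + w]
            if window == pattern or window == tuple(reversed(pattern)):
                span = set(range(start, start + w))
                if region_name in ("AB", "AK", "AH2", "AG", "GAL") and span & claimed:
                    continue  # already explained by a longer A window
                found.append(
                    BreakpointRegion(
                        name=region_name,
                        fragments=arr.fragments[start : start + w],
                        start=start,
                    )
                )
                covered |= span
                if region_name in ("AB", "AK", "AH2", "AG", "GAL"):
                    claimed |= span
    for k in range(n - 1):
        pair = (names[k], names[k + 1])
        if ("A_p" in pair or "A_d" in pair) and not {k, k + 1} <= covered:
            logger.warning(
                "arrangement %s: unknown junction pair %s|%s at position %d "
                "omitted from breakpoint regions",
                arr.name, pair[0], pair[1], k,
            )
    found.sort(key=lambda r: r.start)
    return found


# ---------------------------------------------------------------------------
# A-fragment accounting

def a_fragment_copy_number(arr: Arrangement) -> int:
    """Number of A-fragment copies, counted as A-bearing breakpoint regions.

    E_st and E_1+2 carry one (AB, AG respectively); E_1+2+9 and its
    derivatives carry two (AK or AH2, plus GAL).
    """
    return sum(1 for r in breakpoint_regions(arr) if r.name in ("AB", "AG", "AK", "AH2", "GAL"))


def expected_a_fragment_count(karyotypes: Iterable[Karyotype]) -> int:
    """Total A fragments across individuals, from per-homolog copy numbers."""
    cache: dict[str, int] = {}

    def copies(arr: Arrangement) -> int:
        if arr.name not in cache:
            cache[arr.name] = a_fragment_copy_number(arr)
        return cache[arr.name]

    return sum(copies(k.homolog_1) + copies(k.homolog_2) for k in karyotypes)


#: Synthetic stand-in for the published karyotype survey: pair name -> count.
#: 29 heterokaryotypic individuals over the five arrangements, 36 homologs
#: carrying one A copy (E_st, E_1+2) and 22 carrying two, hence 80 A fragments.
SYNTHETIC_SURVEY_PAIRS: tuple[tuple[str, str, int], ...] = (
    ("E_st", "E_1+2", 9),
    ("E_st", "E_1+2+9", 5),
    ("E_st", "E_1+2+9+3", 3),
    ("E_st", "E_1+2+9+12", 3),
    ("E_1+2", "E_1+2+9", 3),
    ("E_1+2", "E_1+2+9+3", 2),
    ("E_1+2", "E_1+2+9+12", 2),
    ("E_1+2+9", "E_1+2+9+3", 1),
    ("E_1+2+9", "E_1+2+9+12", 1),
)


def synthetic_heterokaryotype_survey() -> list[Karyotype]:
    """A synthetic 29-individual heterokaryotype sample.

    Stand-in karyotype table consistent with the published survey constraints
    (29 heterokaryotypic individuals, five arrangements, 80 expected A
    fragments); the actual per-individual table is not reproduced here.
    """
    canon = canonical_arrangements()
    out: list[Karyotype] = []
    for a, b, count in SYNTHETIC_SURVEY_PAIRS:
        out.extend(Karyotype(canon[a], canon[b]) for _ in range(count))
    return out


# ---------------------------------------------------------------------------
# Dumps

def arrangement_to_records(arr: Arrangement) -> list[dict]:
    """Row-per-fragment records for TSV/JSON dumps."""
    return [
        {
            "arrangement": arr.name,
            "position": i,
            "fragment": f.name,
            "copy_id": f.copy_id,
            "orientation": f.orientation,
            "length_nt": f.length_nt,
            "provenance": f.provenance,
        }
        for i, f in enumerate(arr.fragments)
    ]


def regions_to_records(arr: Arrangement) -> list[dict]:
    return [
        {
            "arrangement": arr.name,
            "region": r.name,
            "start": r.start,
            "fragments": ",".join(f.signed_name for f in r.fragments),
        }
        for r in breakpoint_regions(arr)
    ]
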