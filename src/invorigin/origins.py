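"""Mechanistic models for the origin of inversion E9.

Six mechanisms are implemented.  Three operate on a single chromosome (or its
sister chromatids) carrying the E_1+2 arrangement:

* ``cut_and_paste`` — two breaks, the central segment rejoined inverted;
* ``isochromatid``  — two staggered proximal breaks in one chromatid plus a
  distal break, duplicating the inter-stagger stretch at both breakpoints in
  inverted orientation;
* ``chromatid``     — two breaks in each of two sister chromatids, with the
  same duplication on one sister and the reciprocal deletion on the other.

Three operate on an E_st/E_1+2 heterokaryotype and are the models that can
explain a derived chromosome whose proximal A window (and captured B_p
fragment) descends from the *other* homolog:

* ``nhej4``    — four breaks across both homologs, all repaired by
  non-homologous end joining;
* ``nhej3``    — three breaks (the distal one only on E_1+2);
* ``bir_nhej`` — two breaks on a single E_1+2 chromatid; the proximal break
  repaired by break-induced replication copying A_d and B_p off the E_st
  homolog, the distal break by NHEJ.

All three heterokaryotype mechanisms produce the same derived fragment order
(the E_1+2+9 arrangement); they differ in break count, repair pathways, the
provenance of individual fragments, and their side products.  Each mechanism
also implies a testable constraint on the molecular genealogy of the shared A
fragment, exposed by :func:`predict_clade_constraints`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

from .arrangements import (
    Arrangement,
    ArrangementError,
    Fragment,
    Karyotype,
    assemble,
    breakpoint_regions,
)

HET_MODELS = ("nhej4", "nhej3", "bir_nhej")
SINGLE_CHROMOSOME_MODELS = ("cut_and_paste", "isochromatid", "chromatid")
ALL_MODELS = SINGLE_CHROMOSOME_MODELS + HET_MODELS


class OriginModelError(ValueError):
    """Raised for invalid break specifications or karyotypes."""


@dataclass(frozen=True)
class BreakSpec:
    """A double-strand break at a fragment boundary of a named homolog."""

    homolog: str
    boundary: tuple[str, str]
    scope: str = "chromosome"  # or "chromatid"

    def __post_init__(self) -> None:
        if self.scope not in ("chromosome", "chromatid"):
            raise OriginModelError(f"unknown break scope {self.scope!r}")


@dataclass(frozen=True)
class SideProduct:
    """A non-derived product of the origin event, flagged for survival."""

    arrangement: Arrangement
    surviving: bool


@dataclass(frozen=True)
class OriginOutcome:
    derived: Arrangement
    side_products: tuple[SideProduct, ...]
    n_breaks: int
    pathways: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_breaks < 2:
            raise OriginModelError("an inversion needs at least two breaks")


@dataclass(frozen=True)
class CladeConstraint:
    """Predicted sister relation for A-fragment sequences under a model."""

    focal_regions: frozenset[str]
    predicted_sister: str
    basis: str

    def __post_init__(self) -> None:
        if self.predicted_sister in self.focal_regions:
            raise OriginModelError("focal and sister regions must be disjoint")


# ---------------------------------------------------------------------------
# helpers

def _retag(fragments, provenance: str):
    return tuple(replace(f, provenance=provenance) for f in fragments)


def _inverted(fragments) -> tuple[Fragment, ...]:
    return tuple(f.flipped() for f in reversed(tuple(fragments)))


def _split(arr: Arrangement, spec: BreakSpec) -> int:
    if spec.homolog != arr.name:
        raise OriginModelError(
            f"break on homolog {spec.homolog!r} applied to arrangement {arr.name!r}"
        )
    try:
        return arr.index_of_boundary(spec.boundary)
    except ArrangementError as exc:
        raise OriginModelError(str(exc)) from exc


def _het_pair(het: Karyotype) -> tuple[Arrangement, Arrangement]:
    if not het.is_heterokaryotypic:
        raise OriginModelError("karyotype is homokaryotypic; need E_st/E_1+2")
    by_name = {het.homolog_1.name: het.homolog_1, het.homolog_2.name: het.homolog_2}
    if set(by_name) != {"E_st", "E_1+2"}:
        raise OriginModelError(
            f"heterokaryotype models need E_st/E_1+2, got {sorted(by_name)}"
        )
    return by_name["E_st"], by_name["E_1+2"]


# Break boundaries of the E9 origin (paper-specified, fragment-resolution):
_EST_PROXIMAL = ("B_p", "B_d")   # past the B_p fragment on E_st
_E12_PROXIMAL = ("A_p", "A_d")   # A_p|A_d limit on E_1+2
_DISTAL = ("K", "L")             # the KL breakpoint region


# ---------------------------------------------------------------------------
# single-chromosome mechanisms

def apply_cut_and_paste(arr: Arrangement, b1: BreakSpec, b2: BreakSpec) -> OriginOutcome:
    """Two breaks on one chromosome; the central segment rejoined inverted."""
    if b1.homolog != b2.homolog:
        raise OriginModelError("cut-and-paste breaks must hit the same homolog")
    if b1.boundary == b2.boundary:
        raise OriginModelError("cut-and-paste needs two distinct breaks")
    k1, k2 = sorted((_split(arr, b1), _split(arr, b2)))
    frags = _retag(arr.fragments, arr.name) if arr.name in ("E_st", "E_1+2") else arr.fragments
    derived = assemble(
        "E_1+2+9" if arr.name == "E_1+2" else f"{arr.name}.inverted",
        frags[:k1] + _inverted(frags[k1:k2]) + frags[k2:],
    )
    return OriginOutcome(derived, (), n_breaks=2, pathways=frozenset({"NHEJ"}))


def _staggered_product(
    arr: Arrangement,
    proximal_staggered: tuple[BreakSpec, BreakSpec],
    distal: BreakSpec,
) -> tuple[tuple[Fragment, ...], tuple[Fragment, ...], tuple[Fragment, ...], tuple[Fragment, ...]]:
    """(prefix, stagger, mid, suffix) pieces for the staggered-break models."""
    outer_spec, inner_spec = proximal_staggered
    for spec in (outer_spec, inner_spec, distal):
        if spec.scope != "chromatid":
            raise OriginModelError(
                f"staggered-break models act on chromatids; got scope {spec.scope!r}"
            )
    outer, inner = _split(arr, outer_spec), _split(arr, inner_spec)
    d = _split(arr, distal)
    if outer > inner:
        raise OriginModelError(
            "staggered proximal breaks must be ordered proximal-to-distal"
        )
    if d <= inner:
        raise OriginModelError("distal break must lie distal of the staggered pair")
    frags = _retag(arr.fragments, arr.name) if arr.name in ("E_st", "E_1+2") else arr.fragments
    return frags[:outer], frags[outer:inner], frags[inner:d], frags[d:]


def apply_isochromatid(
    arr: Arrangement,
    proximal_staggered: tuple[BreakSpec, BreakSpec],
    distal: BreakSpec,
) -> OriginOutcome:
    """Two staggered breaks in a single chromatid plus a distal break.

    The stretch between the staggered breaks ends up duplicated at both
    breakpoints of the inverted chromosome, the distal copy in inverted
    orientation.  A zero-width stagger degenerates to the cut-and-paste
    product.
    """
    prefix, stagger, mid, suffix = _staggered_product(arr, proximal_staggered, distal)
    derived = assemble(
        "E_1+2+9" if arr.name == "E_1+2" else f"{arr.name}.inverted",
        prefix + stagger + _inverted(mid) + _inverted(stagger) + suffix,
    )
    return OriginOutcome(derived, (), n_breaks=3, pathways=frozenset({"NHEJ"}))


def apply_chromatid(
    arr: Arrangement,
    breaks: tuple[tuple[BreakSpec, BreakSpec], BreakSpec],
) -> OriginOutcome:
    """Two breaks in each of two sister chromatids.

    One sister inherits the duplication (same derived order as the
    isochromatid model); the reciprocal sister loses the inter-stagger
    stretch at both breakpoints and is flagged non-surviving.
    """
    proximal_staggered, distal = breaks
    prefix, stagger, mid, suffix = _staggered_product(arr, proximal_staggered, distal)
    derived = assemble(
        "E_1+2+9" if arr.name == "E_1+2" else f"{arr.name}.inverted",
        prefix + stagger + _inverted(mid) + _inverted(stagger) + suffix,
    )
    deleted_sister = assemble(
        f"{arr.name}.deleted_sister", prefix + _inverted(mid) + suffix
    )
    return OriginOutcome(
        derived,
        (SideProduct(deleted_sister, surviving=False),),
        n_breaks=4,
        pathways=frozenset({"NHEJ"}),
    )


# ---------------------------------------------------------------------------
# heterokaryotype mechanisms

def apply_nhej4(het: Karyotype) -> OriginOutcome:
    """Four breaks across both homologs, all repaired by NHEJ.

    Staggered proximal breaks (past B_p on E_st, at A_p|A_d on E_1+2) and a
    distal break at the same K|L boundary on both homologs.  The excised
    E_1+2 central segment is rejoined inverted between the external E_st
    pieces.  The reciprocal rejoining is emitted as a non-surviving side
    product.
    """
    e_st, e_12 = _het_pair(het)
    k_st = e_st.index_of_boundary(_EST_PROXIMAL)
    d_st = e_st.index_of_boundary(_DISTAL)
    k_12 = e_12.index_of_boundary(_E12_PROXIMAL)
    d_12 = e_12.index_of_boundary(_DISTAL)

    st = _retag(e_st.fragments, "E_st")
    tw = _retag(e_12.fragments, "E_1+2")
    derived = assemble(
        "E_1+2+9", st[:k_st] + _inverted(tw[k_12:d_12]) + st[d_st:]
    )
    reciprocal = assemble(
        "E9_reciprocal", tw[:k_12] + _inverted(st[k_st:d_st]) + tw[d_12:]
    )
    return OriginOutcome(
        derived,
        (SideProduct(reciprocal, surviving=False),),
        n_breaks=4,
        pathways=frozenset({"NHEJ"}),
    )


def apply_nhej3(het: Karyotype) -> OriginOutcome:
    """Three breaks: staggered proximal pair, distal break on E_1+2 only.

    The derived chromosome keeps the E_1+2 distal tail; the leftover pieces
    rejoin into an E_st chromosome lacking sections A_d and B_p (non-surviving
    side product).
    """
    e_st, e_12 = _het_pair(het)
    k_st = e_st.index_of_boundary(_EST_PROXIMAL)
    k_12 = e_12.index_of_boundary(_E12_PROXIMAL)
    d_12 = e_12.index_of_boundary(_DISTAL)

    st = _retag(e_st.fragments, "E_st")
    tw = _retag(e_12.fragments, "E_1+2")
    derived = assemble(
        "E_1+2+9", st[:k_st] + _inverted(tw[k_12:d_12]) + tw[d_12:]
    )
    broken_est = assemble("E_st.broken", tw[:k_12] + st[k_st:])
    return OriginOutcome(
        derived,
        (SideProduct(broken_est, surviving=False),),
        n_breaks=3,
        pathways=frozenset({"NHEJ"}),
    )


def apply_bir_nhej(het: Karyotype) -> OriginOutcome:
    """Two breaks on one E_1+2 chromatid; BIR proximal repair, NHEJ distal.

    The proximal break invades the E_st homolog and copies its A_d and B_p
    sections (provenance ``E_st``) before the inverted central segment is
    joined on; A_p keeps provenance ``E_1+2``.  The unbroken E_st homolog is
    returned intact among the side products.
    """
    e_st, e_12 = _het_pair(het)
    i_ad = e_12.index_of_boundary(_E12_PROXIMAL)       # start of A_d on E_1+2
    d_12 = e_12.index_of_boundary(_DISTAL)
    # BIR template on E_st: from the homologous A_p|A_d boundary through B_p.
    t_lo = e_st.index_of_boundary(_E12_PROXIMAL)
    t_hi = e_st.index_of_boundary(_EST_PROXIMAL)

    st = _retag(e_st.fragments, "E_st")
    tw = _retag(e_12.fragments, "E_1+2")
    bir_copies = st[t_lo:t_hi]
    derived = assemble(
        "E_1+2+9",
        tw[:i_ad] + bir_copies + _inverted(tw[i_ad:d_12]) + tw[d_12:],
    )
    return OriginOutcome(
        derived,
        (SideProduct(e_st, surviving=True),),
        n_breaks=2,
        pathways=frozenset({"BIR", "NHEJ"}),
    )


def apply_model(model: str, het: Karyotype) -> OriginOutcome:
    """Run a named mechanism with its canonical breaks on ``het``.

    Single-chromosome models take the E_1+2 homolog and apply the E9 breaks
    (A_p|A_d proximal, K|L distal, stagger spanning A_d where applicable).
    """
    e12_name = "E_1+2"
    if model in HET_MODELS:
        fn: Callable[[Karyotype], OriginOutcome] = {
            "nhej4": apply_nhej4,
            "nhej3": apply_nhej3,
            "bir_nhej": apply_bir_nhej,
        }[model]
        return fn(het)
    by_name = {het.homolog_1.name: het.homolog_1, het.homolog_2.name: het.homolog_2}
    if e12_name not in by_name:
        raise OriginModelError("single-chromosome models need an E_1+2 homolog")
    arr = by_name[e12_name]
    outer = BreakSpec(e12_name, ("A_p", "A_d"), scope="chromatid")
    inner = BreakSpec(e12_name, ("A_d", "G"), scope="chromatid")
    distal = BreakSpec(e12_name, ("K", "L"), scope="chromatid")
    if model == "cut_and_paste":
        return apply_cut_and_paste(
            arr,
            BreakSpec(e12_name, ("A_p", "A_d")),
            BreakSpec(e12_name, ("K", "L")),
        )
    if model == "isochromatid":
        return apply_isochromatid(arr, (outer, inner), distal)
    if model == "chromatid":
        return apply_chromatid(arr, ((outer, inner), distal))
    raise OriginModelError(f"unknown origin model {model!r}")


# ---------------------------------------------------------------------------
# genealogical predictions

def predict_clade_constraints(model: str) -> list[CladeConstraint]:
    """Sister-clade predictions for the sequenced A window under each model.

    The sequenced window lies in A_d.  Heterokaryotype models hand the
    proximal A_d (hence the AK/AH2 regions) to the E_st lineage — so those
    sequences should be sister to AB — while the distal duplicated A_d (GAL)
    stays on the E_1+2 lineage with AG.  Single-chromosome models keep every
    A-bearing region on the E_1+2 lineage, predicting all-with-AG.
    """
    if model in HET_MODELS:
        return [
            CladeConstraint(
                frozenset({"AK", "AH2"}),
                "AB",
                basis="proximal A window inherited from the E_st homolog",
            ),
            CladeConstraint(
                frozenset({"GAL"}),
                "AG",
                basis="distal A_d copy carried by the E_1+2 central segment",
            ),
        ]
    if model in ("isochromatid", "chromatid"):
        return [
            CladeConstraint(
                frozenset({"AK", "AH2", "GAL"}),
                "AG",
                basis="both A_d copies duplicated from the single E_1+2 chromosome",
            )
        ]
    if model == "cut_and_paste":
        return [
            CladeConstraint(
                frozenset({"GAL"}),
                "AG",
                basis="single A_d moved to the distal junction of the E_1+2 chromosome",
            )
        ]
    raise OriginModelError(f"unknown origin model {model!r}")


def derived_region_names(outcome: OriginOutcome) -> list[str]:
    """Region names exposed by the derived arrangement."""
    return [r.name for r in breakpoint_regions(outcome.derived)]
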