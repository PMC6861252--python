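"""Polymorphism, divergence and differentiation statistics.

Implements the summary statistics for breakpoint-flank alignments from first
principles: segregating sites, singleton and multiple-hit sites, nucleotide
diversity, haplotype counts, Jukes-Cantor-corrected divergence to an
outgroup, the Hudson-style F_ST estimator ``1 - pi_within / pi_between``,
its label-permutation significance test, and the pairwise region matrix.

Site filtering follows the two standard conventions: *complete deletion*
(drop any column with a gap or ambiguity in any retained sequence, the
default) and *pairwise deletion* (each sequence pair compared over the
columns where both are unambiguous).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import AlignmentError, LabeledAlignment

logger = logging.getLogger(__name__)


class StatisticsError(ValueError):
    pass


class FstUndefinedError(StatisticsError):
    """Raised when pi_between is zero and F_ST has no value."""


@dataclass(frozen=True)
class PolymorphismSummary:
    """Per-group polymorphism and divergence numbers (one table row)."""

    n: int
    sites_used: int
    S: int
    singletons: int
    multihit: int
    pi: float
    h: int
    K: float | None  # None when no outgroup was supplied

    def __post_init__(self) -> None:
        if not (0 <= self.singletons <= self.S <= self.sites_used):
            raise StatisticsError("inconsistent site counts")
        if self.pi < 0 or not (1 <= self.h <= self.n):
            raise StatisticsError("inconsistent diversity or haplotype count")


@dataclass(frozen=True)
class FstResult:
    fst: float
    p_value: float
    n_perm: int
    seed: int | None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise StatisticsError("p-value outside [0, 1]")
        if self.n_perm <= 0:
            raise StatisticsError("n_perm must be positive")


# ---------------------------------------------------------------------------
# column filters

def complete_deletion(aln: LabeledAlignment | np.ndarray) -> np.ndarray:
    """Mask of columns with no gap/ambiguity in any sequence."""
    valid = (
        aln.valid_mask()
        if isinstance(aln, LabeledAlignment)
        else np.isin(np.asarray(aln, dtype="S1"), np.frombuffer(b"ACGT", dtype="S1"))
    )
    if valid.size == 0:
        raise AlignmentError("empty alignment")
    mask = valid.all(axis=0)
    if not mask.any():
        warnings.warn("complete deletion removed every column", stacklevel=2)
    return mask


# ---------------------------------------------------------------------------
# pairwise machinery

def pairwise_counts(
    matrix: np.ndarray, deletion: str = "complete"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair difference and comparable-site counts.

    Returns ``(diffs, sites)``, both ``(n, n)`` symmetric with zero diagonal.
    Under complete deletion every pair shares the same site set; under
    pairwise deletion each pair is compared over its own both-valid columns.
    """
    matrix = np.asarray(matrix, dtype="S1")
    n = matrix.shape[0]
    valid = np.isin(matrix, np.frombuffer(b"ACGT", dtype="S1"))
    if deletion == "complete":
        mask = valid.all(axis=0)
        sub = matrix[:, mask]
        diffs = np.zeros((n, n), dtype=float)
        for i in range(n):
            diffs[i, i + 1 :] = (sub[i + 1 :] != sub[i]).sum(axis=1)
        diffs += diffs.T
        sites = np.full((n, n), float(mask.sum()))
        np.fill_diagonal(sites, 0.0)
        return diffs, sites
    if deletion == "pairwise":
        diffs = np.zeros((n, n), dtype=float)
        sites = np.zeros((n, n), dtype=float)
        for i in range(n):
            both = valid[i + 1 :] & valid[i]
            diffs[i, i + 1 :] = ((matrix[i + 1 :] != matrix[i]) & both).sum(axis=1)
            sites[i, i + 1 :] = both.sum(axis=1)
        diffs += diffs.T
        sites += sites.T
        return diffs, sites
    raise StatisticsError(f"unknown deletion option {deletion!r}")


def _pair_pi(diffs: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Per-pair differences per comparable site (NaN where incomparable)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sites > 0, diffs / np.maximum(sites, 1e-300), np.nan)


def _mean_over_pairs(p: np.ndarray, ia: np.ndarray, ib: np.ndarray | None = None) -> float:
    if ib is None:  # within-group mean over unordered pairs
        block = p[np.ix_(ia, ia)]
        iu = np.triu_indices(len(ia), k=1)
        vals = block[iu]
    else:
        vals = p[np.ix_(ia, ib)].ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise StatisticsError("no comparable sequence pairs")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# polymorphism summary

def jc_correct(p: float | np.ndarray) -> float | np.ndarray:
    """Jukes-Cantor correction ``K = -(3/4) ln(1 - 4p/3)``.

    Raises for ``p >= 0.75`` (saturation) or negative input.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 0.75):
        raise StatisticsError(
            "proportion of differing sites must lie in [0, 0.75) for the "
            "Jukes-Cantor correction"
        )
    out = -0.75 * np.log1p(-4.0 * arr / 3.0)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def summarize_polymorphism(
    aln: LabeledAlignment,
    outgroup: str | int | None = None,
    deletion: str = "complete",
) -> PolymorphismSummary:
    """Polymorphism and divergence summary for the ingroup of ``aln``.

    Site-based counts (S, singletons, multiple-hit sites, haplotypes) and pi
    are computed on the ingroup after the chosen deletion filter; divergence
    K re-filters columns *including* the outgroup sequence and Jukes-Cantor
    corrects the mean ingroup-outgroup difference proportion.

    ``outgroup`` may be a sequence id, an index, or None to use the
    alignment's flagged outgroup (if any).
    """
    og_idx: int | None
    if outgroup is None:
        flagged = aln.outgroup_indices()
        og_idx = int(flagged[0]) if flagged.size else None
    elif isinstance(outgroup, str):
        og_idx = aln.index_of(outgroup)
    else:
        og_idx = int(outgroup)

    in_idx = [i for i in range(aln.n_sequences) if i != og_idx]
    if len(in_idx) < 2:
        raise StatisticsError("need at least two ingroup sequences")
    ingroup = aln.matrix[in_idx]

    valid = np.isin(ingroup, np.frombuffer(b"ACGT", dtype="S1"))
    mask = valid.all(axis=0)
    sub = ingroup[:, mask]
    sites_used = int(mask.sum())

    # site-pattern counts on the completely resolved columns
    S = 0
    singletons = 0
    multihit = 0
    for col in sub.T:
        states, counts = np.unique(col, return_counts=True)
        if len(states) > 1:
            S += 1
            if (counts == 1).any():
                singletons += 1
            if len(states) > 2:
                multihit += 1

    h = len({row.tobytes() for row in sub})

    diffs, sites = pairwise_counts(ingroup, deletion=deletion)
    pi = _mean_over_pairs(_pair_pi(diffs, sites), np.arange(len(in_idx)))

    K = None
    if og_idx is not None:
        full = aln.matrix[in_idx + [og_idx]]
        d2, s2 = pairwise_counts(full, deletion="complete" if deletion == "complete" else "pairwise")
        p2 = _pair_pi(d2, s2)
        n_in = len(in_idx)
        mean_p = _mean_over_pairs(p2, np.arange(n_in), np.array([n_in]))
        K = float(jc_correct(mean_p))

    return PolymorphismSummary(
        n=len(in_idx),
        sites_used=sites_used,
        S=S,
        singletons=singletons,
        multihit=multihit,
        pi=pi,
        h=h,
        K=K,
    )


def polymorphism_table(
    aln: LabeledAlignment, deletion: str = "complete"
) -> pd.DataFrame:
    """Per-region summary plus an Overall column (ingroup jointly)."""
    rows: dict[str, PolymorphismSummary] = {}
    og = aln.outgroup_indices()
    og_list = [int(i) for i in og]
    for region in aln.region_names():
        idx = [int(i) for i in aln.indices_for_region(region) if not aln.outgroup_flags[i]]
        # outgroup auto-detected from the flags carried by the sub-alignment
        rows[region] = summarize_polymorphism(aln.take(idx + og_list), deletion=deletion)
    rows["Overall"] = summarize_polymorphism(aln, deletion=deletion)
    records = {
        name: {
            "n_samples": s.n,
            "n_sites": s.sites_used,
            "S": s.S,
            "singletons": s.singletons,
            "multihit_sites": s.multihit,
            "pi": round(s.pi, 5),
            "haplotypes": s.h,
            "K_jc": None if s.K is None else round(s.K, 5),
        }
        for name, s in rows.items()
    }
    return pd.DataFrame(records, dtype=object)


# ---------------------------------------------------------------------------
# F_ST

def _fst_from_pair_pi(p: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> float:
    pi_a = _mean_over_pairs(p, ia)
    pi_b = _mean_over_pairs(p, ib)
    pi_between = _mean_over_pairs(p, ia, ib)
    if pi_between <= 0:
        raise FstUndefinedError("pi_between is zero; F_ST undefined")
    return 1.0 - 0.5 * (pi_a + pi_b) / pi_between


def fst_hudson(
    aln: LabeledAlignment,
    group_a,
    group_b,
    deletion: str = "complete",
) -> float:
    """Hudson-style ``F_ST = 1 - pi_within / pi_between`` for two groups.

    ``group_a``/``group_b`` are sequence-index collections or region labels;
    pi_within is the unweighted mean of the two within-group diversities.
    """
    ia = _as_indices(aln, group_a)
    ib = _as_indices(aln, group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise StatisticsError("need at least two sequences per group")
    if set(ia) & set(ib):
        raise StatisticsError("groups overlap")
    sel = np.concatenate([ia, ib])
    diffs, sites = pairwise_counts(aln.matrix[sel], deletion=deletion)
    p = _pair_pi(diffs, sites)
    return _fst_from_pair_pi(p, np.arange(len(ia)), np.arange(len(ia), len(sel)))


def _as_indices(aln: LabeledAlignment, group) -> np.ndarray:
    if isinstance(group, str):
        return aln.indices_for_region(group)
    return np.asarray(list(group), dtype=int)


def fst_permutation_p(
    aln: LabeledAlignment,
    groups,
    n_perm: int = 10000,
    seed: int | None = None,
    deletion: str = "complete",
) -> FstResult:
    """Label-permutation test of F_ST between two groups.

    ``groups`` is either a per-sequence label array (exactly two distinct
    labels over the sequences to include) or a pair ``(group_a, group_b)`` of
    index collections / region labels.  Labels are shuffled without
    replacement; the p-value is the fraction of permuted F_ST values strictly
    exceeding the observed one (so an exactly reproduced partition does not
    count against the observed statistic).
    """
    if n_perm <= 0:
        raise StatisticsError("n_perm must be positive")
    if isinstance(groups, (tuple, list)) and len(groups) == 2 and not isinstance(groups[0], str):
        ia, ib = _as_indices(aln, groups[0]), _as_indices(aln, groups[1])
    elif isinstance(groups, (tuple, list)) and len(groups) == 2 and isinstance(groups[0], str):
        ia, ib = _as_indices(aln, groups[0]), _as_indices(aln, groups[1])
    else:
        labels = np.asarray(groups)
        uniq = [u for u in pd.unique(labels) if u is not None]
        if len(uniq) != 2:
            raise StatisticsError("permutation test needs exactly two group labels")
        ia = np.flatnonzero(labels == uniq[0])
        ib = np.flatnonzero(labels == uniq[1])
    if len(ia) < 2 or len(ib) < 2:
        raise StatisticsError("need at least two sequences per group")

    sel = np.concatenate([ia, ib])
    diffs, sites = pairwise_counts(aln.matrix[sel], deletion=deletion)
    p = _pair_pi(diffs, sites)
    na = len(ia)
    observed = _fst_from_pair_pi(p, np.arange(na), np.arange(na, len(sel)))

    rng = np.random.default_rng(seed)
    exceed = 0
    tol = 1e-12 + 1e-9 * abs(observed)
    order = np.arange(len(sel))
    for _ in range(n_perm):
        perm = rng.permutation(order)
        try:
            f = _fst_from_pair_pi(p, perm[:na], perm[na:])
        except FstUndefinedError:
            continue
        if f > observed + tol:
            exceed += 1
    return FstResult(
        fst=observed, p_value=exceed / n_perm, n_perm=n_perm, seed=seed
    )


@dataclass(frozen=True)
class FstMatrix:
    """Pairwise F_ST estimates and permutation p-values between regions."""

    fst: pd.DataFrame
    p_values: pd.DataFrame

    def combined(self) -> pd.DataFrame:
        """Table-style matrix: F_ST below the diagonal, p-values above."""
        regions = list(self.fst.index)
        out = pd.DataFrame("", index=regions, columns=regions, dtype=object)
        for i, a in enumerate(regions):
            for j, b in enumerate(regions):
                if i > j:
                    out.loc[a, b] = f"{self.fst.loc[a, b]:.4f}"
                elif i < j:
                    out.loc[a, b] = f"{self.p_values.loc[a, b]:.4f}"
                else:
                    out.loc[a, b] = "-"
        return out


def fst_matrix(
    aln: LabeledAlignment,
    regions: list[str] | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    deletion: str = "complete",
) -> FstMatrix:
    """All pairwise region F_ST values with permutation p-values."""
    if regions is None:
        regions = aln.region_names()
    if len(regions) < 2:
        raise StatisticsError("need at least two regions for an F_ST matrix")
    fst = pd.DataFrame(np.nan, index=regions, columns=regions)
    pv = pd.DataFrame(np.nan, index=regions, columns=regions)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(regions) * len(regions))
    for i, a in enumerate(regions):
        for j, b in enumerate(regions):
            if j <= i:
                continue
            sub_seed = int(children[i * len(regions) + j].generate_state(1)[0] % (2**31))
            res = fst_permutation_p(
                aln, (a, b), n_perm=n_perm, seed=sub_seed, deletion=deletion
            )
            fst.loc[a, b] = fst.loc[b, a] = res.fst
            pv.loc[a, b] = pv.loc[b, a] = res.p_value
    return FstMatrix(fst=fst, p_values=pv)
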