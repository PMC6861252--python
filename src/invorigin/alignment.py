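"""Labeled multiple-sequence alignment container.

Sequences are stored as a byte matrix over the alphabet ``{A, C, G, T, -, N}``
with one region label, one arrangement label and one outgroup flag per row.
This is the single in-memory exchange object between the simulator, the
polymorphism/differentiation statistics and the tree-building stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Allowed residue codes (upper case; U is normalized to T at read time).
ALPHABET = frozenset(b"ACGT-N")

#: Unambiguous nucleotide codes.
BASES = frozenset(b"ACGT")


class AlignmentError(ValueError):
    """Raised for ragged input, unknown symbols or empty alignments."""


@dataclass
class LabeledAlignment:
    """Equal-length sequences with per-sequence region/arrangement labels.

    Parameters
    ----------
    ids:
        Unique sequence identifiers.
    matrix:
        ``(n_sequences, n_sites)`` array of dtype ``S1``.
    regions:
        Breakpoint-region label per sequence (e.g. ``AB``, ``GAL``,
        ``outgroup``).
    arrangements:
        Chromosomal-arrangement label per sequence (e.g. ``E_st``).
    outgroup_flags:
        True for outgroup sequences.
    """

    ids: list[str]
    matrix: np.ndarray
    regions: list[str]
    arrangements: list[str]
    outgroup_flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        n = self.matrix.shape[0]
        if n == 0:
            raise AlignmentError("empty alignment")
        if not self.outgroup_flags:
            self.outgroup_flags = [False] * n
        for name, values in (
            ("ids", self.ids),
            ("regions", self.regions),
            ("arrangements", self.arrangements),
            ("outgroup_flags", self.outgroup_flags),
        ):
            if len(values) != n:
                raise AlignmentError(
                    f"{name} has {len(values)} entries for {n} sequences"
                )
        if len(set(self.ids)) != n:
            raise AlignmentError("sequence ids must be unique")
        bad = ~np.isin(self.matrix, np.frombuffer(b"ACGT-N", dtype="S1"))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            sym = self.matrix[i, j].decode()
            raise AlignmentError(
                f"unknown symbol {sym!r} in sequence {self.ids[i]!r} "
                f"at column {j}"
            )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_sequences(
        cls,
        ids: Sequence[str],
        sequences: Sequence[str],
        regions: Sequence[str] | None = None,
        arrangements: Sequence[str] | None = None,
        outgroup_flags: Sequence[bool] | None = None,
    ) -> "LabeledAlignment":
        """Build from python strings; normalizes case and U->T."""
        if not sequences:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        norm = [s.upper().replace("U", "T") for s in sequences]
        matrix = np.array([list(s.encode()) for s in norm], dtype=np.uint8).view("S1")
        n = len(sequences)
        return cls(
            ids=list(ids),
            matrix=matrix,
            regions=list(regions) if regions is not None else ["unlabeled"] * n,
            arrangements=(
                list(arrangements) if arrangements is not None else ["unlabeled"] * n
            ),
            outgroup_flags=list(outgroup_flags) if outgroup_flags is not None else None,
        )

    # -- basic queries -----------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, i: int) -> str:
        return self.matrix[i].tobytes().decode()

    def index_of(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def ingroup_indices(self) -> np.ndarray:
        return np.flatnonzero(~np.asarray(self.outgroup_flags))

    def outgroup_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.outgroup_flags))

    def indices_for_region(self, region: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.regions) == region)

    def region_names(self, include_outgroup: bool = False) -> list[str]:
        """Region labels in first-appearance order."""
        seen: list[str] = []
        for r, og in zip(self.regions, self.outgroup_flags):
            if og and not include_outgroup:
                continue
            if r not in seen:
                seen.append(r)
        return seen

    # -- subsetting --------------------------------------------------------

    def take(self, indices: Iterable[int]) -> "LabeledAlignment":
        idx = list(indices)
        return LabeledAlignment(
            ids=[self.ids[i] for i in idx],
            matrix=self.matrix[idx],
            regions=[self.regions[i] for i in idx],
            arrangements=[self.arrangements[i] for i in idx],
            outgroup_flags=[self.outgroup_flags[i] for i in idx],
        )

    def take_columns(self, mask: np.ndarray) -> "LabeledAlignment":
        return LabeledAlignment(
            ids=list(self.ids),
            matrix=self.matrix[:, np.asarray(mask)],
            regions=list(self.regions),
            arrangements=list(self.arrangements),
            outgroup_flags=list(self.outgroup_flags),
        )

    def valid_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` matrix of unambiguous (ACGT) cells."""
        return np.isin(self.matrix, np.frombuffer(b"ACGT", dtype="S1"))
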