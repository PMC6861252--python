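"""FASTA / label-table / config reading and writing.

Labels ride in FASTA headers using the simulator's id format
(``sample_<region>_<arrangement>_<idx>``); a sidecar tab-separated label
table (columns ``id, region, arrangement, outgroup``) overrides them, which
is how real archive records without structured headers are labeled.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import AlignmentError, LabeledAlignment
from .simulate import parse_sample_id


def read_label_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "region"}
    if not required <= set(df.columns):
        raise AlignmentError(
            f"label table {path} must have columns {sorted(required)}"
        )
    if "arrangement" not in df.columns:
        df["arrangement"] = "unlabeled"
    if "outgroup" not in df.columns:
        df["outgroup"] = df["region"].eq("outgroup").astype(int)
    return df.set_index("id")


def write_label_table(aln: LabeledAlignment, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": aln.ids,
            "region": aln.regions,
            "arrangement": aln.arrangements,
            "outgroup": [int(f) for f in aln.outgroup_flags],
        }
    ).to_csv(path, sep="\t", index=False)


def read_fasta(
    path: str | Path, label_table: str | Path | None = None
) -> LabeledAlignment:
    """Read an aligned FASTA into a LabeledAlignment.

    Sequences are upper-cased and U is normalized to T; ragged input or
    symbols outside ``{A,C,G,T,-,N}`` raise with the offending position.
    Labels come from simulator-format headers, overridden by ``label_table``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]

    labels = read_label_table(label_table) if label_table is not None else None
    regions, arrangements, flags = [], [], []
    for seq_id in ids:
        region, arrangement, outgroup = "unlabeled", "unlabeled", False
        parsed = parse_sample_id(seq_id)
        if parsed is not None:
            region, arrangement, _ = parsed
            outgroup = region == "outgroup"
        if labels is not None and seq_id in labels.index:
            row = labels.loc[seq_id]
            region = str(row["region"])
            arrangement = str(row["arrangement"])
            outgroup = bool(int(row["outgroup"]))
        regions.append(region)
        arrangements.append(arrangement)
        flags.append(outgroup)
    return LabeledAlignment.from_sequences(
        ids, seqs, regions=regions, arrangements=arrangements, outgroup_flags=flags
    )


def write_fasta(aln: LabeledAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(aln.sequence(i)), id=aln.ids[i], description="")
        for i in range(aln.n_sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
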