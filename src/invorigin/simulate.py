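"""Synthetic A-fragment alignments under a chosen origin model.

Every inversion arises once, in a single chromosome: at its origin the new
arrangement passes through an extreme single-haplotype bottleneck, and the
breakpoint-flank region then accrues variation only by new mutation (plus,
optionally, rare gene conversion from other arrangements).  The simulator
encodes this as a structured coalescent over per-arrangement pools:

* within a pool, sampled lineages coalesce as a standard neutral coalescent
  with a per-pool effective size (in time units);
* at the pool's origin time all surviving lineages are forced into a single
  founder lineage (the bottleneck), which then joins the parent pool chosen
  by the origin model — the lineage-routing question at the heart of the
  analysis.  Heterokaryotype models attach the AK/AH2 founder to the E_st
  pool; single-chromosome models attach it (coalesced with the GAL founder,
  since both A_d copies then descend from one founding chromosome) to the
  E_1+2 pool.  The GAL founder always descends from E_1+2;
* an outgroup lineage splits from the ingroup ancestor at the deepest time.

Mutations are Poisson on branch lengths with Jukes-Cantor substitution.
Time units are arbitrary; defaults are calibrated so that per-region
diversity and outgroup divergence land in the empirically observed ranges
(see docs/methods.md).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .alignment import LabeledAlignment
from .origins import ALL_MODELS, HET_MODELS

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Pool holding the AK + AH2 complex (arrangements E_1+2+9 and E_1+2+9+12
#: pooled: the E_12 inversion does not touch the E_9 breakpoints).
COMPLEX_POOL = "E_[1+2+9]"

OUTGROUP_ID = "sample_outgroup_D_guanche_0"

_HEADER_RE = re.compile(r"^sample_(AB|AG|AK|AH2|GAL|outgroup)_(.+)_(\d+)$")


class SimulationError(ValueError):
    pass


def _default_times() -> dict[str, float]:
    return {"outgroup": 9.0, "E_1+2": 5.0, "E_9": 2.0, "E_3": 1.0, "E_12": 1.5}


def _default_samples() -> dict[str, int]:
    return {"AB": 18, "AG": 6, "GAL": 10, "AK": 11, "AH2": 5}


@dataclass
class SimParams:
    """Simulation knobs; defaults reproduce the study's sampling design."""

    seq_length: int = 2000
    mu: float = 0.005                      # substitutions / site / time unit
    origin_times: dict[str, float] = field(default_factory=_default_times)
    sample_sizes: dict[str, int] = field(default_factory=_default_samples)
    model: str = "nhej3"
    pool_ne: float = 1.0                   # coalescent effective size, time units
    gene_conversion_rate: float = 0.0      # events / lineage / time unit
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seq_length <= 0:
            raise SimulationError("seq_length must be positive")
        if self.mu < 0:
            raise SimulationError("mu must be non-negative")
        if self.pool_ne <= 0:
            raise SimulationError("pool_ne must be positive")
        if self.gene_conversion_rate < 0:
            raise SimulationError("gene_conversion_rate must be non-negative")
        if any(v < 0 for v in self.sample_sizes.values()):
            raise SimulationError("sample sizes must be non-negative")
        t = self.origin_times
        required = ("outgroup", "E_1+2", "E_9", "E_3")
        if any(k not in t for k in required + ("E_12",)):
            raise SimulationError(f"origin_times must define {required + ('E_12',)}")
        if not (t["outgroup"] > t["E_1+2"] > t["E_9"] > t["E_3"] > 0):
            raise SimulationError(
                "origin times must be strictly ordered "
                "outgroup > E_1+2 > E_9 > E_3 > 0"
            )
        if not (t["E_9"] > t["E_12"] > 0):
            raise SimulationError("E_12 must postdate E_9 (E_9 > E_12 > 0)")


@dataclass(frozen=True)
class PoolSpec:
    name: str
    origin_time: float | None   # None for the root (ancestral) pool
    parent: str | None


@dataclass(frozen=True)
class HistoryGraph:
    """Lineage-descent structure implied by an origin model."""

    model: str
    pools: dict[str, PoolSpec]
    region_pool: dict[str, str]
    gal_coupled: bool           # single-chromosome models: both A_d copies
                                # descend from one founding chromosome

    def edges(self) -> list[tuple[str, str, float]]:
        return [
            (p.name, p.parent, p.origin_time)
            for p in self.pools.values()
            if p.parent is not None
        ]

    def founder_parent(self, region: str) -> str:
        """Pool into which a region's founder lineage is grafted."""
        pool = self.pools[self.region_pool[region]]
        while pool.parent is not None and pool.origin_time is None:
            pool = self.pools[pool.parent]
        if pool.parent is None:
            raise SimulationError(f"region {region} sits on the root lineage")
        return pool.parent


def build_history(model: str, params: SimParams) -> HistoryGraph:
    """Descent graph for ``model``: who each founder lineage descends from."""
    if model not in ALL_MODELS:
        raise SimulationError(f"unknown origin model {model!r}")
    t = params.origin_times
    het = model in HET_MODELS
    pools = {
        "E_st": PoolSpec("E_st", None, None),
        "E_1+2": PoolSpec("E_1+2", t["E_1+2"], "E_st"),
        COMPLEX_POOL: PoolSpec(
            COMPLEX_POOL, t["E_9"], "E_st" if het else "E_1+2"
        ),
        "E_1+2+9+3": PoolSpec("E_1+2+9+3", t["E_3"], COMPLEX_POOL),
        "GAL": PoolSpec("GAL", t["E_9"], "E_1+2"),
    }
    region_pool = {
        "AB": "E_st",
        "AG": "E_1+2",
        "AK": COMPLEX_POOL,
        "AH2": "E_1+2+9+3",
        "GAL": "GAL",
    }
    return HistoryGraph(
        model=model, pools=pools, region_pool=region_pool, gal_coupled=not het
    )


# ---------------------------------------------------------------------------
# genealogy

class GeneNode:
    """Minimal genealogy node: coalescence time and children."""

    __slots__ = ("time", "children", "name")

    def __init__(self, time: float, children: Iterable["GeneNode"] = (), name: str | None = None):
        self.time = time
        self.children = list(children)
        self.name = name

    def leaves(self) -> list["GeneNode"]:
        if not self.children:
            return [self]
        out: list[GeneNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.children:
                stack.extend(node.children)
            else:
                out.append(node)
        return out

    def newick(self) -> str:
        def rec(node: GeneNode, parent_time: float) -> str:
            bl = parent_time - node.time
            if not node.children:
                return f"{node.name}:{bl:.6g}"
            inner = ",".join(rec(c, node.time) for c in node.children)
            return f"({inner}):{bl:.6g}"

        inner = ",".join(rec(c, self.time) for c in self.children)
        return f"({inner});"


def mrca_time(root: GeneNode, leaf_names: set[str]) -> float:
    """Time of the smallest clade containing all named leaves."""
    best = [root.time]

    def rec(node: GeneNode) -> set[str]:
        if not node.children:
            return {node.name} if node.name in leaf_names else set()
        got: set[str] = set()
        for c in node.children:
            got |= rec(c)
        if got >= leaf_names and node.time < best[0]:
            best[0] = node.time
        return got

    found = rec(root)
    if not found >= leaf_names:
        raise SimulationError("leaf names missing from genealogy")
    return best[0]


def _coalesce_pools(
    pools: dict[str, list[GeneNode]],
    t: float,
    t_end: float,
    ne: float,
    rng: np.random.Generator,
) -> float:
    """Run within-pool Kingman coalescence from ``t`` until ``t_end``."""
    while True:
        names = [p for p, mem in pools.items() if len(mem) >= 2]
        rates = [len(pools[p]) * (len(pools[p]) - 1) / (2.0 * ne) for p in names]
        total = sum(rates)
        if total == 0.0:
            return t_end
        t_next = t + rng.exponential(1.0 / total)
        if t_next >= t_end:
            return t_end
        t = t_next
        r = rng.random() * total
        acc = 0.0
        for p, rate in zip(names, rates):
            acc += rate
            if r <= acc:
                members = pools[p]
                i, j = sorted(rng.choice(len(members), size=2, replace=False))
                node = GeneNode(t, [members[i], members[j]])
                members[j : j + 1] = []
                members[i] = node
                break
        else:  # numerical edge: attribute to the last pool
            members = pools[names[-1]]
            i, j = sorted(rng.choice(len(members), size=2, replace=False))
            node = GeneNode(t, [members[i], members[j]])
            members[j : j + 1] = []
            members[i] = node


def simulate_genealogy(
    params: SimParams, history: HistoryGraph, rng: np.random.Generator
) -> tuple[GeneNode, list[GeneNode]]:
    """Draw one sample genealogy; returns (root, leaves incl. outgroup)."""
    leaves: list[GeneNode] = []
    pools: dict[str, list[GeneNode]] = {p: [] for p in history.pools}
    arrangement_of = _arrangement_assignments(params.sample_sizes)
    for region in ("AB", "AG", "GAL", "AK", "AH2"):
        for idx in range(params.sample_sizes.get(region, 0)):
            name = f"sample_{region}_{arrangement_of[region][idx]}_{idx}"
            leaf = GeneNode(0.0, name=name)
            leaves.append(leaf)
            pools[history.region_pool[region]].append(leaf)
    if sum(len(m) for m in pools.values()) == 0:
        raise SimulationError("no ingroup samples requested")

    t_out = params.origin_times["outgroup"]
    boundaries = sorted(
        {p.origin_time for p in history.pools.values() if p.origin_time is not None}
    )
    t = 0.0
    for tb in boundaries:
        t = _coalesce_pools(pools, t, tb, params.pool_ne, rng)
        due = sorted(
            p.name
            for p in history.pools.values()
            if p.origin_time == tb
        )
        founders: dict[str, GeneNode | None] = {}
        for name in due:
            members = pools[name]
            if not members:
                founders[name] = None
            elif len(members) == 1:
                founders[name] = members[0]
            else:
                founders[name] = GeneNode(tb, list(members))  # bottleneck
            pools[name] = []
        if history.gal_coupled and COMPLEX_POOL in due and "GAL" in due:
            a, b = founders.pop(COMPLEX_POOL), founders.pop("GAL")
            joint = (
                GeneNode(tb, [a, b]) if a is not None and b is not None
                else a if a is not None else b
            )
            if joint is not None:
                pools[history.pools[COMPLEX_POOL].parent].append(joint)
        for name, node in founders.items():
            if node is not None:
                pools[history.pools[name].parent].append(node)

    t = _coalesce_pools(pools, t, t_out, params.pool_ne, rng)
    remaining = [node for mem in pools.values() for node in mem]
    ingroup = remaining[0] if len(remaining) == 1 else GeneNode(t_out, remaining)
    outgroup = GeneNode(0.0, name=OUTGROUP_ID)
    leaves.append(outgroup)
    root = GeneNode(t_out, [ingroup, outgroup])
    return root, leaves


def _arrangement_assignments(sample_sizes: dict[str, int]) -> dict[str, list[str]]:
    """Deterministic arrangement label per sample within each region."""
    out: dict[str, list[str]] = {}
    out["AB"] = ["E_st"] * sample_sizes.get("AB", 0)
    out["AG"] = ["E_1+2"] * sample_sizes.get("AG", 0)
    out["AK"] = [
        "E_1+2+9" if i % 2 == 0 else "E_1+2+9+12"
        for i in range(sample_sizes.get("AK", 0))
    ]
    out["AH2"] = ["E_1+2+9+3"] * sample_sizes.get("AH2", 0)
    gal_cycle = ("E_1+2+9", "E_1+2+9+3", "E_1+2+9+12")
    out["GAL"] = [gal_cycle[i % 3] for i in range(sample_sizes.get("GAL", 0))]
    return out


# ---------------------------------------------------------------------------
# sequences

def _evolve_sequences(
    root: GeneNode, seq_length: int, mu: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Drop Jukes-Cantor mutations down the genealogy; returns leaf codes."""
    out: dict[str, np.ndarray] = {}
    root_seq = rng.integers(0, 4, size=seq_length, dtype=np.int8)
    stack: list[tuple[GeneNode, np.ndarray]] = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in node.children:
            bl = node.time - child.time
            if bl < 0:
                raise SimulationError("negative branch length in genealogy")
            cseq = seq.copy()
            n_mut = rng.poisson(bl * mu * seq_length)
            if n_mut:
                sites = rng.integers(0, seq_length, size=n_mut)
                steps = rng.integers(1, 4, size=n_mut)
                for s, k in zip(sites, steps):  # sequential: multiple hits allowed
                    cseq[s] = (cseq[s] + k) % 4
            if child.children:
                stack.append((child, cseq))
            else:
                out[child.name] = cseq
    return out


def _apply_gene_conversion(
    seqs: dict[str, np.ndarray],
    rate: float,
    total_time: float,
    rng: np.random.Generator,
) -> None:
    """Tip-level gene-conversion approximation: copy random tracts between
    sampled sequences.  Captures the homogenizing effect of conversion
    between arrangements without tracking donor lineages through time."""
    if rate <= 0:
        return
    names = sorted(seqs)
    n_events = rng.poisson(rate * len(names) * total_time)
    for _ in range(n_events):
        r, d = rng.choice(len(names), size=2, replace=False)
        length = int(rng.integers(50, 501))
        L = len(seqs[names[r]])
        start = int(rng.integers(0, max(1, L - length + 1)))
        seqs[names[r]][start : start + length] = seqs[names[d]][start : start + length]


@dataclass
class SimulatedDataset:
    """One synthetic dataset: alignment, truth genealogy and history."""

    alignment: LabeledAlignment
    history: HistoryGraph
    genealogy: GeneNode
    params: SimParams

    def genealogy_newick(self) -> str:
        return self.genealogy.newick()

    def truth_json(self) -> str:
        return json.dumps(
            {
                "model": self.history.model,
                "edges": self.history.edges(),
                "gal_coupled": self.history.gal_coupled,
                "params": {
                    k: v
                    for k, v in asdict(self.params).items()
                    if k not in ("origin_times", "sample_sizes")
                },
                "origin_times": self.params.origin_times,
                "sample_sizes": self.params.sample_sizes,
                "genealogy": self.genealogy_newick(),
            },
            indent=2,
        )


def parse_sample_id(seq_id: str) -> tuple[str, str, int] | None:
    """(region, arrangement, index) from a simulator-format FASTA id."""
    m = _HEADER_RE.match(seq_id)
    if m is None:
        return None
    return m.group(1), m.group(2), int(m.group(3))


def simulate_alignment(params: SimParams) -> SimulatedDataset:
    """Simulate one labeled alignment under ``params.model``."""
    rng = np.random.default_rng(params.seed)
    history = build_history(params.model, params)
    root, leaves = simulate_genealogy(params, history, rng)
    seqs = _evolve_sequences(root, params.seq_length, params.mu, rng)
    _apply_gene_conversion(
        seqs, params.gene_conversion_rate, params.origin_times["outgroup"], rng
    )

    ids, rows, regions, arrangements, flags = [], [], [], [], []
    for leaf in leaves:
        parsed = parse_sample_id(leaf.name)
        region, arrangement, _ = parsed
        ids.append(leaf.name)
        rows.append(_BASES[seqs[leaf.name]])
        regions.append(region)
        arrangements.append(arrangement)
        flags.append(region == "outgroup")
    aln = LabeledAlignment(
        ids=ids,
        matrix=np.vstack(rows),
        regions=regions,
        arrangements=arrangements,
        outgroup_flags=flags,
    )
    return SimulatedDataset(alignment=aln, history=history, genealogy=root, params=params)
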