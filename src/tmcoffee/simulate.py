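"""Synthetic membrane-protein families with column-exact ground truth.

Families are evolved on a star tree from a sampled ancestor whose
architecture alternates loops with hydrophobic membrane-spanning segments.
Substitutions are slower inside the membrane segments (configurable
multiplier) and indels are confined to loops by default, so the true
alignment and its core blocks (the membrane-segment columns) stay
well-defined through every edit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .formats import (AA20, GAP, CoreAnnotation, MultipleAlignment, Sequence)

# hydrophobic pool used for membrane-spanning segments, polar-enriched pool
# for loops
TM_POOL = "AILMFVWYGC"
TM_WEIGHTS = (8.0, 10.0, 12.0, 3.0, 6.0, 10.0, 2.0, 3.0, 5.0, 2.0)
LOOP_POOL = "ACDEFGHIKLMNPQRSTVWY"
LOOP_WEIGHTS = (6.0, 1.0, 7.0, 7.0, 2.0, 7.0, 3.0, 3.0, 7.0, 4.0,
                2.0, 6.0, 6.0, 5.0, 6.0, 8.0, 6.0, 4.0, 1.0, 3.0)


@dataclass(frozen=True)
class TopologyModel:
    """Architecture of a simulated membrane protein."""

    n_tm: int = 3
    tm_len: tuple[int, int] = (15, 30)
    loop_len: tuple[int, int] = (5, 15)
    tm_pool: str = TM_POOL
    tm_weights: tuple[float, ...] = TM_WEIGHTS
    loop_pool: str = LOOP_POOL
    loop_weights: tuple[float, ...] = LOOP_WEIGHTS

    def __post_init__(self) -> None:
        if self.n_tm < 1:
            raise ConfigError("need at least one membrane segment")
        lo, hi = self.tm_len
        if not (5 <= lo <= hi <= 30):
            raise ConfigError("membrane-segment length range must lie "
                              "within [5, 30]")
        llo, lhi = self.loop_len
        if not (0 < llo <= lhi):
            raise ConfigError("invalid loop length range")
        if any(w <= 0 for w in self.tm_weights + self.loop_weights):
            raise ConfigError("pool weights must be positive")
        if (len(self.tm_pool) != len(self.tm_weights)
                or len(self.loop_pool) != len(self.loop_weights)):
            raise ConfigError("pool and weight lengths differ")


@dataclass(frozen=True)
class SimulatedFamily:
    """A star-tree family with its column-exact true alignment."""

    ancestor: Sequence
    segments: tuple[tuple[int, int], ...]   # TM spans on the ancestor
    descendants: tuple[Sequence, ...]
    truth: MultipleAlignment
    core: CoreAnnotation
    seed: int
    #: ancestor threaded into truth columns (gap at insertion columns)
    ancestor_row: str = ""

    def __post_init__(self) -> None:
        degapped = self.truth.degapped()
        for d in self.descendants:
            if degapped[d.id] != d.residues:
                raise DataError(
                    f"true alignment row {d.id!r} does not degap to the "
                    "descendant sequence")


def _sample_pool(rng: np.random.Generator, pool: str,
                 weights: tuple[float, ...], n: int) -> str:
    p = np.asarray(weights, dtype=float)
    p /= p.sum()
    return "".join(rng.choice(list(pool), size=n, p=p))


def sample_ancestor(topology: TopologyModel, seed: int
                    ) -> tuple[Sequence, tuple[tuple[int, int], ...]]:
    """Alternating loop/TM/... architecture; returns the sequence plus the
    0-based half-open membrane-segment spans."""
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    segments: list[tuple[int, int]] = []
    pos = 0
    for k in range(topology.n_tm + 1):
        llen = int(rng.integers(topology.loop_len[0],
                                topology.loop_len[1] + 1))
        parts.append(_sample_pool(rng, topology.loop_pool,
                                  topology.loop_weights, llen))
        pos += llen
        if k < topology.n_tm:
            tlen = int(rng.integers(topology.tm_len[0],
                                    topology.tm_len[1] + 1))
            parts.append(_sample_pool(rng, topology.tm_pool,
                                      topology.tm_weights, tlen))
            segments.append((pos, pos + tlen))
            pos += tlen
    return (Sequence(f"anc{seed}", "".join(parts), "transmembrane ancestor"),
            tuple(segments))


def _tm_mask(length: int, segments) -> np.ndarray:
    m = np.zeros(length, dtype=bool)
    for s, e in segments:
        m[s:e] = True
    return m


def _substitute(rng: np.random.Generator, residues: str, mask: np.ndarray,
                rate: float, tm_multiplier: float) -> str:
    site_rate = np.where(mask, rate * tm_multiplier, rate)
    hit = rng.random(len(residues)) < site_rate
    out = list(residues)
    for p in np.nonzero(hit)[0]:
        # substitute with a uniformly chosen different residue
        choices = [a for a in AA20 if a != out[p]]
        out[p] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def evolve_family(ancestor: Sequence, segments, n_descendants: int,
                  sub_rate: float, indel_rate: float, seed: int, *,
                  tm_multiplier: float = 0.3,
                  indels_in_tm: bool = False,
                  indel_extend: float = 0.5,
                  id_prefix: str | None = None) -> SimulatedFamily:
    """Star-tree evolution with truth tracked column-exactly.

    Each descendant applies substitutions (slower inside membrane segments)
    followed by loop-confined indels: per loop site, deletion or insertion
    each with probability ``indel_rate / 2``; insertion lengths are
    geometric with continuation probability ``indel_extend``.
    """
    if not (0.0 <= sub_rate < 1.0 and 0.0 <= indel_rate < 1.0):
        raise ConfigError("rates must lie in [0, 1)")
    if n_descendants < 2:
        raise ConfigError("need at least 2 descendants")
    rng = np.random.default_rng(seed)
    L = len(ancestor)
    mask = _tm_mask(L, segments)
    prefix = id_prefix if id_prefix is not None else ancestor.id
    names = [f"{prefix}_d{k}" for k in range(n_descendants)]

    kept: list[np.ndarray] = []          # per descendant: ancestor site kept?
    residues_at: list[list[str]] = []    # per descendant: residue per site
    inserts: list[dict[int, str]] = []   # per descendant: junction -> string
    for _ in names:
        subbed = _substitute(rng, ancestor.residues, mask, sub_rate,
                             tm_multiplier)
        keep = np.ones(L, dtype=bool)
        ins: dict[int, str] = {}
        for p in range(L):
            if mask[p] and not indels_in_tm:
                continue
            if rng.random() < indel_rate / 2.0:
                keep[p] = False
            if rng.random() < indel_rate / 2.0:
                n_ins = int(rng.geometric(1.0 - indel_extend))
                ins[p] = _sample_pool(rng, LOOP_POOL, LOOP_WEIGHTS, n_ins)
        kept.append(keep)
        residues_at.append(list(subbed))
        inserts.append(ins)

    # column layout: [pre-insertions at junction -1]* then, per ancestor
    # site p: the site column, then each descendant's insertion after p
    rows: list[list[str]] = [[] for _ in names]

    def emit_insertions(junction: int) -> None:
        for d in range(len(names)):
            s = inserts[d].get(junction, "")
            for ch in s:
                for e in range(len(names)):
                    rows[e].append(ch if e == d else GAP)

    site_col = np.full(L, -1, dtype=np.int64)
    emit_insertions(-1)
    for p in range(L):
        site_col[p] = len(rows[0])
        for d in range(len(names)):
            rows[d].append(residues_at[d][p] if kept[d][p] else GAP)
        emit_insertions(p)

    anc_row = [GAP] * len(rows[0])
    for p in range(L):
        anc_row[site_col[p]] = ancestor.residues[p]

    descendants = []
    truth_rows = []
    for d, name in enumerate(names):
        row = "".join(rows[d])
        truth_rows.append(row)
        descendants.append(Sequence(name, row.replace(GAP, ""),
                                    "transmembrane simulated"))
    truth = MultipleAlignment(tuple(names), tuple(truth_rows))
    core_spans = tuple((int(site_col[s]), int(site_col[e - 1]) + 1)
                       for s, e in segments)
    core = CoreAnnotation({name: core_spans for name in names},
                          columns=truth.ncols)
    return SimulatedFamily(ancestor=ancestor, segments=tuple(segments),
                           descendants=tuple(descendants), truth=truth,
                           core=core, seed=seed, ancestor_row="".join(anc_row))


def rate_for_identity(target_identity: float, tm_fraction: float,
                      tm_multiplier: float = 0.3) -> float:
    """Substitution rate whose expected sequence identity to the ancestor is
    ``target_identity`` given the membrane-segment fraction of sites."""
    eff = (1.0 - tm_fraction) + tm_multiplier * tm_fraction
    return min(0.99, (1.0 - target_identity) / eff)


def make_family(seed: int, *, n_members: int = 5, n_tm: int = 3,
                target_identity: float = 0.7,
                indel_rate: float = 0.03,
                topology: TopologyModel | None = None,
                tm_multiplier: float = 0.3) -> SimulatedFamily:
    """Convenience wrapper: sample an ancestor and evolve a family whose
    members sit near the requested identity to the ancestor."""
    topology = topology or TopologyModel(n_tm=n_tm)
    ancestor, segments = sample_ancestor(topology, seed)
    tm_fraction = sum(e - s for s, e in segments) / len(ancestor)
    rate = rate_for_identity(target_identity, tm_fraction, tm_multiplier)
    return evolve_family(ancestor, segments, n_members, rate, indel_rate,
                         seed + 1, tm_multiplier=tm_multiplier,
                         id_prefix=f"fam{seed}")


def build_mini_database(families, n_decoys: int,
                        decoy_len_range: tuple[int, int] = (80, 200),
                        seed: int = 0, *, relatives_per_member: int = 2,
                        branch_point: tuple[float, float] = (0.3, 0.7),
                        relative_noise: float = 0.05) -> list[Sequence]:
    """Family members, close relatives inside the hit-filter identity band,
    and random decoys; family-derived records carry the keyword
    ``transmembrane`` in their descriptions, decoys do not.

    Relatives branch off partway along a member's branch: per site the
    relative takes the member state with the branch-point probability and
    the ancestral state otherwise, then accrues its own noise.  This keeps
    them 50-90% identical to the member while carrying family-wide signal,
    mirroring how database homologs relate to a real family.
    """
    rng = np.random.default_rng(seed)
    records: list[Sequence] = []
    for fam in families:
        anc_row = fam.ancestor_row or GAP * fam.truth.ncols
        for member in fam.descendants:
            records.append(member)
            mrow = fam.truth.row(member.id)
            for r in range(relatives_per_member):
                alpha = rng.uniform(*branch_point)
                chars = []
                for mc, ac in zip(mrow, anc_row):
                    if mc == GAP:
                        continue
                    ch = mc if (ac == GAP or rng.random() < alpha) else ac
                    if rng.random() < relative_noise:
                        others = [a for a in AA20 if a != ch]
                        ch = others[int(rng.integers(len(others)))]
                    chars.append(ch)
                records.append(Sequence(f"{member.id}_h{r}", "".join(chars),
                                        "transmembrane homolog"))
    for k in range(n_decoys):
        n = int(rng.integers(decoy_len_range[0], decoy_len_range[1] + 1))
        res = "".join(rng.choice(list(AA20), size=n))
        records.append(Sequence(f"decoy{k}", res, "random decoy"))
    return records
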