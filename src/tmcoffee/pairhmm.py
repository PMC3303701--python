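"""Profile-adapted pair-HMM with bi-phasic gaps: posterior decoding and
constraint extraction.

The model has five states — one match and two insert-state pairs carrying
distinct open/extend probabilities for short and long gaps.  The match state
emits the expected likelihood ratio of two profile columns; insert states
emit at background odds (ratio 1), so posteriors are invariant to the null
model.  A column's gap mass is removed by renormalizing over the 20 residues
before taking the expectation; optionally the score is scaled by the product
of the two columns' occupancies so that sparsely supported profile ends do
not generate confident constraints.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import _hmm_core
from .errors import ConfigError, DataError
from .formats import AA20

logger = logging.getLogger(__name__)

N_STATES = 5
MATCH = 0

#: version string of the bundled default parameter file
DEFAULT_PARAMS_RESOURCE = "probcons_params.json"


@dataclass(frozen=True)
class PairHmmParams:
    """Transition/emission parameters of the 5-state bi-phasic pair-HMM."""

    init: np.ndarray          # (5,) initial state distribution
    gap_open: np.ndarray      # (2,) short, long
    gap_extend: np.ndarray    # (2,) short, long
    emission: np.ndarray      # (20, 20) joint residue-pair distribution
    background: np.ndarray    # (20,) background residue frequencies
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if abs(float(self.init.sum()) - 1.0) > 1e-9:
            raise ConfigError("initial distribution must sum to 1")
        if not np.all(self.emission > 0):
            raise ConfigError("emission matrix entries must be positive")
        if abs(float(self.emission.sum()) - 1.0) > 1e-6:
            raise ConfigError("emission matrix must sum to 1")
        if np.max(np.abs(self.emission - self.emission.T)) > 1e-12:
            raise ConfigError("emission matrix must be symmetric")
        if not np.all(self.background > 0):
            raise ConfigError("background frequencies must be positive")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ConfigError("background frequencies must sum to 1")
        t = self.transitions
        if np.max(np.abs(t.sum(axis=1) - 1.0)) > 1e-9:
            raise ConfigError("transition rows must sum to 1")
        if np.any(t < 0):
            raise ConfigError("transition probabilities must be non-negative")

    @property
    def transitions(self) -> np.ndarray:
        go1, go2 = self.gap_open
        ge1, ge2 = self.gap_extend
        t = np.zeros((N_STATES, N_STATES))
        t[0, 0] = 1.0 - 2.0 * go1 - 2.0 * go2
        t[0, 1] = t[0, 2] = go1
        t[0, 3] = t[0, 4] = go2
        for s, ge in ((1, ge1), (2, ge1), (3, ge2), (4, ge2)):
            t[s, s] = ge
            t[s, 0] = 1.0 - ge
        return t

    @property
    def lr_matrix(self) -> np.ndarray:
        """Joint emission divided by the product of backgrounds."""
        return self.emission / np.outer(self.background, self.background)

    @classmethod
    def from_dict(cls, d: dict) -> "PairHmmParams":
        alphabet = d.get("alphabet", AA20)
        if alphabet != AA20:
            order = [alphabet.index(a) for a in AA20]
        else:
            order = list(range(20))
        em = np.asarray(d["emission"], dtype=float)[np.ix_(order, order)]
        bg = np.asarray(d["background"], dtype=float)[order]
        init = np.asarray(d["init_distrib"], dtype=float)
        init = init / init.sum()  # published values sum to 1 - 7e-8
        return cls(
            init=init,
            gap_open=np.asarray(d["gap_open"], dtype=float),
            gap_extend=np.asarray(d["gap_extend"], dtype=float),
            emission=em,
            background=bg,
            version=str(d.get("version", "unversioned")),
        )

    @classmethod
    def default(cls) -> "PairHmmParams":
        with resources.files("tmcoffee.data").joinpath(
                DEFAULT_PARAMS_RESOURCE).open() as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_file(cls, path) -> "PairHmmParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class PosteriorMatrix:
    """Posterior match probabilities between two profiles plus the total
    log-odds of the pair under the model."""

    probs: np.ndarray
    loglik: float

    def __post_init__(self) -> None:
        p = self.probs
        if np.any(p < 0) or np.any(p > 1 + 1e-9):
            raise DataError("posterior entries must lie in [0,1]")
        if p.size:
            if np.any(p.sum(axis=1) > 1 + 1e-6) or np.any(p.sum(axis=0) > 1 + 1e-6):
                raise DataError("posterior row/column sums exceed 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape


def _renormalize(col: np.ndarray) -> tuple[np.ndarray, float]:
    """Split a 21-letter profile column into residue frequencies
    (renormalized over the 20 residues) and occupancy (1 - gap mass)."""
    res = col[:20]
    tot = float(res.sum())
    if tot <= 0.0:
        return np.full(20, 0.05), 0.0
    return res / tot, tot


def column_emission_score(colA: np.ndarray, colB: np.ndarray,
                          params: PairHmmParams) -> float:
    """Expected match-emission likelihood ratio of two profile columns."""
    fa, occA = _renormalize(np.asarray(colA, dtype=float))
    fb, occB = _renormalize(np.asarray(colB, dtype=float))
    if occA == 0.0 or occB == 0.0:
        logger.warning("all-gap profile column: neutral emission score")
        return 1.0
    return float(fa @ params.lr_matrix @ fb)


def emission_matrix(profA, profB, params: PairHmmParams,
                    occupancy: bool = True) -> np.ndarray:
    """Match-emission likelihood ratios for every column pair of two
    ExtendedProfiles, optionally scaled by the occupancy product."""
    fa = profA.freqs[:, :20]
    fb = profB.freqs[:, :20]
    occA = fa.sum(axis=1)
    occB = fb.sum(axis=1)
    emptyA = occA <= 0.0
    emptyB = occB <= 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(emptyA[:, None], 0.05, fa / np.where(emptyA, 1.0, occA)[:, None])
        fb = np.where(emptyB[:, None], 0.05, fb / np.where(emptyB, 1.0, occB)[:, None])
    E = fa @ params.lr_matrix @ fb.T
    if occupancy:
        E = E * np.outer(np.where(emptyA, 1.0, occA),
                         np.where(emptyB, 1.0, occB))
    # all-gap columns score neutrally
    if emptyA.any():
        logger.warning("profile %s has all-gap columns", profA.query.id)
        E[emptyA, :] = 1.0
    if emptyB.any():
        logger.warning("profile %s has all-gap columns", profB.query.id)
        E[:, emptyB] = 1.0
    return E


def forward_backward(profA, profB, params: PairHmmParams,
                     occupancy: bool = True) -> PosteriorMatrix:
    """Posterior match probabilities between two profiles by the
    forward-backward algorithm in log space."""
    if profA.freqs.shape[0] == 0 or profB.freqs.shape[0] == 0:
        raise DataError("profiles must be non-empty")
    E = emission_matrix(profA, profB, params, occupancy=occupancy)
    return forward_backward_from_emissions(E, params)


def forward_backward_from_emissions(E: np.ndarray,
                                    params: PairHmmParams) -> PosteriorMatrix:
    logE = np.log(E)
    lt = np.log(np.where(params.transitions > 0, params.transitions, 1e-300))
    lt[params.transitions == 0] = -np.inf
    linit = np.log(params.init)
    F = _hmm_core.forward(logE, lt, linit)
    B = _hmm_core.backward(logE, lt)
    total_f = _hmm_core.total_from_forward(F)
    total_b = _hmm_core.total_from_backward(B, logE, linit)
    if not np.isfinite(total_f):
        raise DataError("pair-HMM total likelihood underflowed")
    if abs(total_f - total_b) > 1e-6 * max(1.0, abs(total_f)):
        raise DataError(
            f"forward/backward totals disagree: {total_f} vs {total_b}")
    P = _hmm_core.match_posteriors(F, B, total_f)
    return PosteriorMatrix(probs=P, loglik=float(total_f))


def extract_constraints(post: PosteriorMatrix, seqA_id: str, seqB_id: str,
                        threshold: float = 0.99) -> list[tuple[int, int, int]]:
    """Cells with posterior strictly above ``threshold``, weighted by the
    posterior scaled to integer percent (ties at .5 round half up)."""
    if not (0.0 < threshold <= 1.0):
        raise ConfigError(f"posterior threshold {threshold} outside (0,1]")
    ii, jj = np.nonzero(post.probs > threshold)
    out = []
    for i, j in zip(ii.tolist(), jj.tolist()):
        w = int(np.floor(post.probs[i, j] * 100.0 + 0.5))
        out.append((i, j, w))
    return out
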