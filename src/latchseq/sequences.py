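"""Categorical sequence metrics for latch-opening sequences.

This module implements the sequence-analysis core used to characterise
extractive-foraging technique at a multi-compartment puzzle box:

* **longitudinal entropy** — Shannon entropy (nats) of the within-sequence
  distribution of latch types, ignoring order;
* **transition count** — number of adjacent positions where the latch type
  changes;
* **complexity index** — geometric mean of normalised transition rate and
  normalised entropy, 0 for a single-latch sequence and 1 for equal use of
  all latches with a switch at every step;
* **optimal matching (OM)** — minimum-cost edit distance between two
  sequences with insertion/deletion cost ``c_indel`` and a substitution
  cost matrix derived from observed transition rates
  (``cost(i, j) = c_val - p(i->j) - p(j->i)``);
* length **normalisation** and **intra/inter-individual partition** of the
  pairwise distance matrix.

The alphabet is the four latch types of the multi-solution box:
H (horizontal side-pull bolt), R (rod removal), V (vertical pull-down bolt),
S (rotating swivel).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ALPHABET",
    "LatchSequence",
    "ComplexityResult",
    "TransitionMatrix",
    "SubstitutionCostMatrix",
    "DistanceMatrix",
    "longitudinal_entropy",
    "transition_count",
    "complexity_index",
    "estimate_transition_rates",
    "trate_costs",
    "om_distance",
    "normalize_distance",
    "pairwise_distances",
    "partition_dissimilarities",
]

#: The four latch types of the multi-solution puzzle box.
ALPHABET: tuple[str, ...] = ("H", "R", "V", "S")


@dataclass(frozen=True)
class LatchSequence:
    """An ordered categorical sequence of latch types with trial metadata.

    Parameters
    ----------
    states
        Ordered latch types, each a member of ``alphabet``.
    individual_id, trial_index, condition
        Metadata carried through the dissimilarity analyses. ``condition``
        is one of ``"unrestricted"``, ``"competitive"`` or ``"undetermined"``.
    alphabet
        The state space. Defaults to the four-latch alphabet.
    """

    states: tuple[str, ...]
    individual_id: str = ""
    trial_index: int = 0
    condition: str = "undetermined"
    alphabet: tuple[str, ...] = ALPHABET

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError("a LatchSequence must contain at least one state")
        bad = set(self.states) - set(self.alphabet)
        if bad:
            raise ValueError(
                f"states {sorted(bad)} outside alphabet {self.alphabet}"
            )

    @classmethod
    def from_string(cls, s: str, **meta) -> "LatchSequence":
        """Build a sequence from a compact string such as ``"SHVS"``."""
        return cls(states=tuple(s), **meta)

    def __len__(self) -> int:
        return len(self.states)

    def __str__(self) -> str:
        return "".join(self.states)


@dataclass(frozen=True)
class ComplexityResult:
    """Entropy, transition count and the combined complexity index."""

    h: float
    h_max: float
    q: int
    q_max: int
    C: float


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic first-order transition probabilities with raw counts."""

    P: np.ndarray
    counts: np.ndarray
    alphabet: tuple[str, ...] = ALPHABET

    def index(self, state: str) -> int:
        return self.alphabet.index(state)


@dataclass(frozen=True)
class SubstitutionCostMatrix:
    """Symmetric zero-diagonal state-pair substitution costs plus indel cost."""

    costs: np.ndarray
    alphabet: tuple[str, ...] = ALPHABET
    c_val: float = 2.0
    c_indel: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.costs, dtype=float)
        if c.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("cost matrix shape does not match alphabet")
        if not np.allclose(c, c.T):
            raise ValueError("substitution cost matrix must be symmetric")
        if np.any(np.diag(c) != 0):
            raise ValueError("substitution cost diagonal must be zero")

    def cost(self, a: str, b: str) -> float:
        i = self.alphabet.index(a)
        j = self.alphabet.index(b)
        return float(self.costs[i, j])

    @classmethod
    def constant(
        cls,
        c_val: float = 2.0,
        c_indel: float = 1.0,
        alphabet: tuple[str, ...] = ALPHABET,
    ) -> "SubstitutionCostMatrix":
        """Uniform off-diagonal cost ``c_val`` (the classic OM default)."""
        k = len(alphabet)
        c = np.full((k, k), float(c_val))
        np.fill_diagonal(c, 0.0)
        return cls(costs=c, alphabet=alphabet, c_val=c_val, c_indel=c_indel)


@dataclass
class DistanceMatrix:
    """Pairwise OM distances (raw and normalised) with per-row labels.

    ``labels[k]`` is ``(individual_id, trial_index, condition)`` for row k.
    """

    d: np.ndarray
    d_norm: np.ndarray
    labels: list[tuple[str, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return self.d.shape[0]


def _validate_states(seq: LatchSequence, alphabet: tuple[str, ...]) -> None:
    bad = set(seq.states) - set(alphabet)
    if bad:
        raise ValueError(f"states {sorted(bad)} outside alphabet {alphabet}")


def longitudinal_entropy(
    seq: LatchSequence, alphabet: tuple[str, ...] | None = None
) -> float:
    """Shannon entropy (nats) of the within-sequence state distribution.

    Invariant under permutation of positions; 0 for a single-state
    sequence and ``ln(len(alphabet))`` at equal state counts.
    """
    alphabet = alphabet if alphabet is not None else seq.alphabet
    _validate_states(seq, alphabet)
    n = len(seq)
    h = 0.0
    for a in alphabet:
        c = seq.states.count(a)
        if c > 0:
            p = c / n
            h -= p * math.log(p)
    return h


def transition_count(seq: LatchSequence) -> int:
    """Number of adjacent positions at which the state changes."""
    return sum(
        1 for a, b in zip(seq.states[:-1], seq.states[1:]) if a != b
    )


def complexity_index(
    seq: LatchSequence, alphabet: tuple[str, ...] | None = None
) -> ComplexityResult:
    """Complexity index: sqrt of normalised transitions times normalised entropy.

    ``C = sqrt((q / (n - 1)) * (h / ln|A|))`` with the full alphabet used for
    ``h_max`` regardless of how many states the sequence visits. A sequence
    of length 1 cannot switch, so its complexity is defined as 0.
    """
    alphabet = alphabet if alphabet is not None else seq.alphabet
    h = longitudinal_entropy(seq, alphabet)
    h_max = math.log(len(alphabet))
    q = transition_count(seq)
    q_max = len(seq) - 1
    if q_max == 0:
        return ComplexityResult(h=h, h_max=h_max, q=0, q_max=0, C=0.0)
    C = math.sqrt((q / q_max) * (h / h_max))
    return ComplexityResult(h=h, h_max=h_max, q=q, q_max=q_max, C=C)


def estimate_transition_rates(
    seqs: list[LatchSequence], alphabet: tuple[str, ...] = ALPHABET
) -> TransitionMatrix:
    """Pool adjacent-pair counts over sequences into transition probabilities.

    Rows with no observed outgoing transitions get a uniform distribution so
    the matrix stays row-stochastic. Raises if no sequence contributes a
    transition (all have length 1).
    """
    k = len(alphabet)
    idx = {a: i for i, a in enumerate(alphabet)}
    counts = np.zeros((k, k), dtype=float)
    for seq in seqs:
        _validate_states(seq, alphabet)
        for a, b in zip(seq.states[:-1], seq.states[1:]):
            counts[idx[a], idx[b]] += 1
    if counts.sum() == 0:
        raise ValueError(
            "no transitions observed: all sequences have length 1"
        )
    P = np.empty_like(counts)
    for i in range(k):
        row_sum = counts[i].sum()
        P[i] = counts[i] / row_sum if row_sum > 0 else 1.0 / k
    return TransitionMatrix(P=P, counts=counts, alphabet=alphabet)


def trate_costs(
    tm: TransitionMatrix, c_val: float = 2.0, c_indel: float = 1.0
) -> SubstitutionCostMatrix:
    """Transition-rate substitution costs: ``c_val - p(i->j) - p(j->i)``.

    States that frequently follow one another are cheap to substitute.
    Costs are clipped below at zero (which can only bind when
    ``p(i->j) + p(j->i) > c_val``) and the diagonal is zero.
    """
    if c_val <= 0:
        raise ValueError("c_val must be positive")
    sc = c_val - tm.P - tm.P.T
    np.fill_diagonal(sc, 0.0)
    sc = np.clip(sc, 0.0, None)
    return SubstitutionCostMatrix(
        costs=sc, alphabet=tm.alphabet, c_val=c_val, c_indel=c_indel
    )


def om_distance(
    s1: LatchSequence | tuple[str, ...] | str,
    s2: LatchSequence | tuple[str, ...] | str,
    sc: SubstitutionCostMatrix,
) -> float:
    """Optimal-matching edit distance by the standard dynamic programme.

    Minimum total cost of insertions/deletions (``sc.c_indel`` each) and
    substitutions (``sc.costs``) transforming ``s1`` into ``s2``. Symmetric
    when the cost matrix is symmetric; ``om_distance(s, s) == 0``.
    """
    a = tuple(s1.states if isinstance(s1, LatchSequence) else s1)
    b = tuple(s2.states if isinstance(s2, LatchSequence) else s2)
    idx = {s: i for i, s in enumerate(sc.alphabet)}
    try:
        ai = [idx[s] for s in a]
        bi = [idx[s] for s in b]
    except KeyError as e:
        raise ValueError(f"state {e.args[0]!r} outside alphabet") from None
    n, m = len(ai), len(bi)
    ci = sc.c_indel
    costs = sc.costs
    prev = [j * ci for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [i * ci] + [0.0] * m
        si = ai[i - 1]
        row = costs[si]
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + ci,
                cur[j - 1] + ci,
                prev[j - 1] + row[bi[j - 1]],
            )
        prev = cur
    return float(prev[m])


def normalize_distance(
    d: float, n1: int, n2: int, method: str = "longest"
) -> float:
    """Length-normalise a raw OM distance.

    ``"longest"`` divides by ``max(n1, n2)`` (the classic sequence-analysis
    normalisation for this distance); ``"sum"`` divides by ``n1 + n2``;
    ``"none"`` returns ``d`` unchanged.
    """
    if method == "longest":
        return d / max(n1, n2)
    if method == "sum":
        return d / (n1 + n2)
    if method == "none":
        return d
    raise ValueError(f"unknown normalization method {method!r}")


def pairwise_distances(
    seqs: list[LatchSequence],
    sc: SubstitutionCostMatrix,
    normalize: bool = True,
    method: str = "longest",
) -> DistanceMatrix:
    """Full symmetric matrix of (normalised) OM distances between sequences."""
    m = len(seqs)
    if m < 2:
        raise ValueError("need at least 2 sequences")
    d = np.zeros((m, m))
    d_norm = np.zeros((m, m))
    for k, l in itertools.combinations(range(m), 2):
        dist = om_distance(seqs[k], seqs[l], sc)
        d[k, l] = d[l, k] = dist
        dn = (
            normalize_distance(dist, len(seqs[k]), len(seqs[l]), method)
            if normalize
            else dist
        )
        d_norm[k, l] = d_norm[l, k] = dn
    labels = [(s.individual_id, s.trial_index, s.condition) for s in seqs]
    return DistanceMatrix(d=d, d_norm=d_norm, labels=labels)


def partition_dissimilarities(
    dm: DistanceMatrix, condition: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split off-diagonal normalised distances into intra- and inter-individual.

    ``intra`` holds distances between trials of the same individual, ``inter``
    between trials of different individuals; together they cover every
    unordered off-diagonal pair exactly once. If ``condition`` is given, only
    rows with that condition label enter the partition.
    """
    rows = [
        k
        for k, lab in enumerate(dm.labels)
        if condition is None or lab[2] == condition
    ]
    intra: list[float] = []
    inter: list[float] = []
    for k, l in itertools.combinations(rows, 2):
        val = float(dm.d_norm[k, l])
        if dm.labels[k][0] == dm.labels[l][0]:
            intra.append(val)
        else:
            inter.append(val)
    return np.asarray(intra), np.asarray(inter)
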