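"""Model-based pairwise evolutionary distances from a multiple alignment.

Implements the p-distance, the Kimura two-parameter (K2P) correction

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

with P and Q the transition and transversion difference proportions, and
the Tamura–Nei (TN93) closed form, which separates purine (A<->G) and
pyrimidine (C<->T) transitions and uses empirical base frequencies.  The
"maximum composite likelihood"-style variant (``TN93-MCL``) applies the
TN93 form with base frequencies pooled across the whole alignment rather
than re-estimated per pair, which shares one global rate structure among
all pairs.

Gap and ambiguous columns are removed either per pair (pairwise deletion)
or from every comparison (complete deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome_compare import MultipleAlignment

__all__ = ["SitePairCounts", "DistanceMatrix", "count_site_pairs",
           "p_distance", "k2p_distance", "tn93_distance",
           "build_distance_matrix", "encode_alignment"]

# base order used throughout the numerics: A, C, G, T
BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class SitePairCounts:
    """Per-pair site difference proportions and base frequencies.

    P/Q are transition/transversion difference proportions; P1 (A<->G,
    purine) and P2 (C<->T, pyrimidine) split P for the TN93 form.  Base
    frequencies are averaged over the two sequences unless pooled
    frequencies are supplied by the caller.
    """

    P: float
    Q: float
    P1: float
    P2: float
    base_freqs: tuple[float, float, float, float]   # piA, piC, piG, piT
    n_sites: int

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("no comparable sites")
        if self.P + self.Q > 1.0 + 1e-12:
            raise ValueError("P + Q exceeds 1")


@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances (substitutions/site)."""

    taxa: list[str]
    d: np.ndarray
    model: str = "p"
    deletion_policy: str = "complete"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.d[i, j])

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.taxa)]
        for name, row in zip(self.taxa, self.d):
            lines.append(name + "\t" + "\t".join(f"{x:.10g}" for x in row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Encoding and counting


def encode_alignment(rows: Sequence[str]) -> np.ndarray:
    """Integer-encode gapped rows: A,C,G,T -> 0..3, everything else -> 4."""
    lookup = np.full(256, 4, dtype=np.int8)
    for b, i in _CODE.items():
        lookup[ord(b)] = i
        lookup[ord(b.lower())] = i
    mat = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return lookup[mat].reshape(len(rows), -1)


def count_site_pairs(row_i: str, row_j: str, policy: str = "pairwise",
                     complete_mask: Optional[np.ndarray] = None,
                     pooled_freqs: Optional[Sequence[float]] = None
                     ) -> SitePairCounts:
    """Difference proportions between two gapped rows of one MSA.

    Under pairwise deletion, sites with a gap/ambiguity in either row are
    skipped; under complete deletion the caller's whole-alignment mask
    (``complete_mask``) defines the retained sites.  ``pooled_freqs``
    overrides the per-pair empirical base frequencies (used by the
    composite-likelihood style matrix).
    """
    enc = encode_alignment([row_i, row_j])
    return _count_encoded(enc[0], enc[1], policy, complete_mask, pooled_freqs)


def _count_encoded(a: np.ndarray, b: np.ndarray, policy: str,
                   complete_mask: Optional[np.ndarray],
                   pooled_freqs: Optional[Sequence[float]],
                   weights: Optional[np.ndarray] = None) -> SitePairCounts:
    ok = (a < 4) & (b < 4)
    if policy == "complete":
        if complete_mask is None:
            raise ValueError("complete deletion needs the whole-MSA mask")
        ok &= complete_mask
    elif policy != "pairwise":
        raise ValueError(f"unknown deletion policy {policy!r}")
    if weights is None:
        weights = np.ones(a.shape[0])
    w = weights[ok]
    n = w.sum()
    if n == 0:
        raise ValueError("zero comparable sites for this pair")
    ai, bi = a[ok], b[ok]
    diff = ai != bi
    # transitions: A(0)<->G(2) and C(1)<->T(3) — index parity differs by 2
    ts = diff & (np.abs(ai - bi) == 2)
    p1 = w[ts & (ai % 2 == 0)].sum() / n      # purine transitions
    p2 = w[ts & (ai % 2 == 1)].sum() / n      # pyrimidine transitions
    q = w[diff & ~ts].sum() / n
    if pooled_freqs is not None:
        freqs = tuple(float(x) for x in pooled_freqs)
    else:
        counts = np.zeros(4)
        for k in range(4):
            counts[k] = w[ai == k].sum() + w[bi == k].sum()
        freqs = tuple(counts / counts.sum())
    return SitePairCounts(P=float(p1 + p2), Q=float(q), P1=float(p1),
                          P2=float(p2), base_freqs=freqs, n_sites=int(round(n)))


# ---------------------------------------------------------------------------
# Closed-form distances


def p_distance(c: SitePairCounts) -> float:
    return c.P + c.Q


def k2p_distance(c: SitePairCounts) -> float:
    """Kimura (1980) two-parameter distance; saturation -> inf."""
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    return -0.5 * math.log(w1 * math.sqrt(w2))


def tn93_distance(c: SitePairCounts) -> float:
    """Tamura & Nei (1993) distance with empirical frequencies; saturation -> inf.

    Degenerate frequency configurations (a missing purine or pyrimidine)
    fall back to the K2P form, which is the model's own limit there.
    """
    pi_a, pi_c, pi_g, pi_t = c.base_freqs
    pi_r, pi_y = pi_a + pi_g, pi_c + pi_t
    if pi_a * pi_g == 0.0 or pi_c * pi_t == 0.0:
        return k2p_distance(c)
    k1 = 2.0 * pi_a * pi_g / pi_r
    k2 = 2.0 * pi_t * pi_c / pi_y
    k3 = 2.0 * (pi_r * pi_y - pi_a * pi_g * pi_y / pi_r - pi_t * pi_c * pi_r / pi_y)
    w1 = 1.0 - c.P1 / k1 - c.Q / (2.0 * pi_r)
    w2 = 1.0 - c.P2 / k2 - c.Q / (2.0 * pi_y)
    w3 = 1.0 - c.Q / (2.0 * pi_r * pi_y)
    if w1 <= 0.0 or w2 <= 0.0 or w3 <= 0.0:
        return math.inf
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


_MODELS = {"p": p_distance, "K2P": k2p_distance, "TN93": tn93_distance,
           "TN93-MCL": tn93_distance}


def build_distance_matrix(msa: MultipleAlignment, model: str = "TN93-MCL",
                          policy: str = "complete",
                          pattern_weights: Optional[tuple[np.ndarray, np.ndarray]] = None
                          ) -> DistanceMatrix:
    """All-pairs distance matrix under a named model and deletion policy.

    ``TN93-MCL`` pools base frequencies across the whole alignment (all
    rows, retained sites) so that every pair shares one frequency vector;
    the per-pair difference proportions remain pair-specific.  Other models
    use per-pair empirical frequencies.

    ``pattern_weights`` — optional (encoded columns, weights) pair used by
    the bootstrap machinery to reweight compressed site patterns instead of
    materializing resampled alignments.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_MODELS)}")
    if len(msa.ids) < 3:
        raise ValueError("need at least 3 rows")
    if pattern_weights is not None:
        enc, weights = pattern_weights
    else:
        enc = encode_alignment(msa.rows)
        weights = np.ones(enc.shape[1])
    mask = None
    if policy == "complete":
        mask = np.all(enc < 4, axis=0)
        if not mask.any():
            raise ValueError("complete deletion removed every column")
    pooled = None
    if model == "TN93-MCL":
        sel = mask if mask is not None else np.ones(enc.shape[1], bool)
        counts = np.zeros(4)
        for k in range(4):
            counts[k] = (weights[None, :] * ((enc == k) & sel[None, :])).sum()
        pooled = counts / counts.sum()
    n = len(msa.ids)
    d = np.zeros((n, n))
    dist_fn = _MODELS[model]
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            counts = _count_encoded(enc[i], enc[j], policy, mask, pooled,
                                    weights=weights)
            val = dist_fn(counts)
            if math.isinf(val):
                saturated.append((msa.ids[i], msa.ids[j]))
            d[i, j] = d[j, i] = val
    if saturated:
        raise ValueError(f"saturated pairs under {model}: {saturated}")
    return DistanceMatrix(taxa=list(msa.ids), d=d, model=model,
                          deletion_policy=policy)
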